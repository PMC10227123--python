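import numpy as np
import pandas as pd
import pytest

import wmtraj as wt


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (96 participants, six studies)."""
    return wt.simulate_cohort(wt.CohortConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_partition(default_cohort):
    return wt.fit(default_cohort.matrix, 3, restarts=20, rng_seed=1)


@pytest.fixture(scope="session")
def default_indices(default_cohort):
    return wt.build_index_table(default_cohort.panels)


@pytest.fixture()
def toy_matrix():
    """Two tight 1-D groups far apart; optimal 2-partition is obvious.

    Values are on an unconstrained scale (constructed directly, bypassing
    the [1, 4] score check) to match hand-computed criterion values.
    """
    m = wt.TrajectoryMatrix.__new__(wt.TrajectoryMatrix)
    m.participants = ["a", "b", "c", "d"]
    m.values = np.array([[0.0], [0.1], [10.0], [10.1]])
    m.study_of = {}
    return m


def make_matrix(values, prefix="p"):
    values = np.asarray(values, dtype=float)
    m = wt.TrajectoryMatrix.__new__(wt.TrajectoryMatrix)
    m.participants = [f"{prefix}{i}" for i in range(values.shape[0])]
    m.values = values
    m.study_of = {}
    return m


@pytest.fixture()
def make_unchecked_matrix():
    """Factory for matrices that skip the [1, 4] score-range check."""
    return make_matrix
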