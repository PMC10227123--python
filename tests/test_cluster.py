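import itertools

import numpy as np
import pytest

import wmtraj as wt
from wmtraj.cluster import _recompute_seeds, _pairwise_sq_dist
from conftest import make_matrix


def within_total(values, labels, seeds, T):
    W = 0.0
    for c in np.unique(labels):
        for v in values[labels == c]:
            W += wt.trajectory_distance(v, seeds[c - 1], T) ** 2
    return W


def enumeration_optimum(values, k=2):
    """Brute-force minimum within-cluster squared distance over all k-partitions."""
    n, T = values.shape
    best = np.inf
    for assignment in itertools.product(range(1, k + 1), repeat=n):
        labels = np.array(assignment)
        if len(np.unique(labels)) < k:
            continue
        seeds = _recompute_seeds(values, labels, k)
        best = min(best, within_total(values, labels, seeds, T))
    return best


class TestTrajectoryDistance:
    def test_identity_is_zero(self):
        x = np.array([1.0, 2.5, np.nan, 4.0])
        assert wt.trajectory_distance(x, x, 4) == 0.0

    def test_complete_pair_hand_value(self):
        d = wt.trajectory_distance(np.array([1.0, 3.0]), np.array([2.0, 5.0]), 2)
        assert d == pytest.approx(np.sqrt(5), abs=1e-12)

    def test_missing_inflation_factor(self):
        x = np.array([1.0, np.nan, np.nan])
        y = np.array([2.0, np.nan, np.nan])
        assert wt.trajectory_distance(x, y, 3) == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_disjoint_support_is_incomparable(self):
        x = np.array([1.0, np.nan])
        y = np.array([np.nan, 2.0])
        assert wt.trajectory_distance(x, y, 2) == np.inf


class TestKmeansppInit:
    def test_k_equals_n_uses_every_trajectory(self):
        vals = np.arange(1, 4, 0.5).reshape(-1, 1) + np.zeros((1, 2))
        m = make_matrix(np.clip(vals, 1, 4))
        seeds = wt.kmeanspp_init(m, m.n, np.random.default_rng(0))
        assert sorted(seeds[:, 0].tolist()) == sorted(m.values[:, 0].tolist())

    def test_k_below_2_rejected(self):
        m = make_matrix(np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="k must be >= 2"):
            wt.kmeanspp_init(m, 1, np.random.default_rng(0))

    def test_k_above_n_rejected(self):
        m = make_matrix(np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="exceeds"):
            wt.kmeanspp_init(m, 3, np.random.default_rng(0))

    def test_d2_sampling_splits_distant_groups(self):
        """Monte-Carlo check of the squared-distance seeding rule."""
        rng = np.random.default_rng(0)
        vals = np.vstack(
            [
                1.0 + rng.normal(0, 0.01, (5, 2)),
                3.9 + rng.normal(0, 0.01, (5, 2)),
            ]
        )
        m = make_matrix(np.clip(vals, 1, 4))
        hits = 0
        runs = 2000
        for i in range(runs):
            seeds = wt.kmeanspp_init(m, 2, np.random.default_rng(i))
            hits += seeds[:, 0].min() < 2.0 < seeds[:, 0].max()
        assert hits / runs >= 0.99


class TestFit:
    def test_toy_two_group_case_is_enumeration_optimal(self, make_unchecked_matrix):
        vals = np.array([[0.0, 0.0], [0.1, 0.1], [10.0, 10.0], [10.1, 10.1]])
        m = make_unchecked_matrix(vals)
        for seed in range(5):
            part = wt.fit_once(m, 2, np.random.default_rng(seed))
            sets = {frozenset(np.flatnonzero(part.labels == c)) for c in (1, 2)}
            assert sets == {frozenset({0, 1}), frozenset({2, 3})}

    def test_identical_trajectories_fixed_point_after_one_pass(self):
        m = make_matrix(np.full((5, 3), 2.0))
        part = wt.fit_once(m, 2, np.random.default_rng(0))
        assert part.converged

    def test_fixed_point_reassignment_is_idempotent(self, default_partition,
                                                    default_cohort):
        d2 = _pairwise_sq_dist(
            default_cohort.matrix.values, default_partition.seeds
        )
        np.testing.assert_array_equal(
            np.argmin(d2, axis=1) + 1, default_partition.labels
        )

    def test_every_cluster_nonempty_and_seeds_are_member_means(
        self, default_partition, default_cohort
    ):
        sizes = default_partition.sizes()
        assert (sizes > 0).all() and sizes.sum() == 96
        expected = _recompute_seeds(
            default_cohort.matrix.values, default_partition.labels, 3
        )
        np.testing.assert_allclose(
            default_partition.seeds, expected, equal_nan=True, atol=1e-12
        )

    def test_restarted_fit_is_deterministic(self, default_cohort):
        p1 = wt.fit(default_cohort.matrix, 3, restarts=5, rng_seed=42)
        p2 = wt.fit(default_cohort.matrix, 3, restarts=5, rng_seed=42)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.criteria == p2.criteria

    def test_more_restarts_never_lower_the_selection_criterion(
        self, default_cohort
    ):
        one = wt.fit(default_cohort.matrix, 3, restarts=1, rng_seed=9)
        many = wt.fit(default_cohort.matrix, 3, restarts=20, rng_seed=9)
        assert many.criteria["ch1"] >= one.criteria["ch1"]

    def test_permuting_rows_preserves_membership_sets(self, default_cohort):
        m = default_cohort.matrix
        rng = np.random.default_rng(3)
        perm = rng.permutation(m.n)
        m2 = m.subset(perm)
        p1 = wt.fit(m, 3, restarts=5, rng_seed=11)
        p2 = wt.fit(m2, 3, restarts=5, rng_seed=11)
        a1, a2 = p1.assignments, p2.assignments
        assert all(a1[p] == a2[p] for p in m.participants)


class TestValidityCriteria:
    def test_toy_calinski_harabasz_hand_value(self, toy_matrix):
        part = wt.fit(toy_matrix, 2, restarts=3, rng_seed=0)
        assert wt.calinski_harabasz(part, toy_matrix, 1) == pytest.approx(
            20000.0, rel=1e-9
        )

    def test_toy_ray_turi_hand_value(self, toy_matrix):
        part = wt.fit(toy_matrix, 2, restarts=3, rng_seed=0)
        assert wt.ray_turi(part, toy_matrix) == pytest.approx(-2.5e-5, rel=1e-9)

    def test_ch_variants_ordering_on_toy(self, toy_matrix):
        part = wt.fit(toy_matrix, 2, restarts=3, rng_seed=0)
        ratio = wt.calinski_harabasz(part, toy_matrix, 3)
        assert wt.calinski_harabasz(part, toy_matrix, 1) == pytest.approx(2 * ratio)
        assert wt.calinski_harabasz(part, toy_matrix, 2) == pytest.approx(1.5 * ratio)

    def test_complete_data_agrees_with_sklearn_reference(self, default_cohort,
                                                         default_partition):
        """Variant-3 (raw trace ratio) cross-checked against scikit-learn.

        On complete rows the adjusted distance reduces to plain Euclidean,
        so B/W must match sklearn's score rescaled by its df factor.
        """
        from sklearn.metrics import calinski_harabasz_score

        complete = ~np.isnan(default_cohort.matrix.values).any(axis=1)
        idx = np.flatnonzero(complete)
        sub = default_cohort.matrix.subset(idx)
        part = wt.fit(sub, 3, restarts=5, rng_seed=0)
        ours = wt.calinski_harabasz(part, sub, 1)
        theirs = calinski_harabasz_score(sub.values, part.labels)
        assert ours == pytest.approx(theirs, rel=1e-8)

    def test_random_labels_on_noise_follow_the_F_null(self,
                                                      make_unchecked_matrix):
        """Labels independent of i.i.d. noise: CH-1 is F(k-1, n-k) distributed
        (between-cluster matches within-cluster scatter per df, ratio ~ 1)."""
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        scores = []
        n, k = 200, 3
        for _ in range(300):
            vals = rng.normal(size=(n, 1))
            labels = rng.integers(1, k + 1, size=n)
            m = make_unchecked_matrix(vals)
            seeds = _recompute_seeds(vals, labels, k)
            part = wt.Partition(
                k=k, participants=m.participants, labels=labels, seeds=seeds, n=n
            )
            scores.append(wt.calinski_harabasz(part, m, 1))
        ks = sps.kstest(scores, sps.f(k - 1, n - k).cdf)
        assert ks.pvalue > 0.005
        assert np.median(scores) == pytest.approx(
            sps.f(k - 1, n - k).median(), rel=0.2
        )

    def test_zero_between_scatter_gives_zero_criterion(self,
                                                       make_unchecked_matrix):
        vals = np.array([[1.0], [3.0], [1.0], [3.0]])
        labels = np.array([1, 1, 2, 2])  # both clusters have the same mean
        seeds = _recompute_seeds(vals, labels, 2)
        m = make_unchecked_matrix(vals)
        part = wt.Partition(k=2, participants=m.participants, labels=labels,
                            seeds=seeds, n=4)
        assert wt.calinski_harabasz(part, m, 1) == pytest.approx(0.0)

    def test_duplicate_seed_degenerate_partition_hits_sentinel(
        self, make_unchecked_matrix
    ):
        vals = np.array([[1.0], [3.0], [1.0], [3.0]])
        labels = np.array([1, 1, 2, 2])
        seeds = _recompute_seeds(vals, labels, 2)
        m = make_unchecked_matrix(vals)
        part = wt.Partition(k=2, participants=m.participants, labels=labels,
                            seeds=seeds, n=4)
        with pytest.warns(UserWarning, match="coincident"):
            assert wt.ray_turi(part, m) == -np.inf
        with pytest.warns(UserWarning, match="coincident"):
            assert wt.davies_bouldin(part, m) == -np.inf

    def test_zero_within_scatter_infinite_ch(self, make_unchecked_matrix):
        vals = np.array([[1.0], [1.0], [3.0], [3.0]])
        m = make_unchecked_matrix(vals)
        part = wt.fit(m, 2, restarts=2, rng_seed=0)
        with pytest.warns(UserWarning, match="infinite"):
            assert wt.calinski_harabasz(part, m, 1) == np.inf


class TestCriterionSweep:
    def test_single_k_report_standardizes_to_zero(self, default_cohort):
        rep = wt.criterion_sweep(
            default_cohort.matrix, k_range=[2], restarts=3, rng_seed=0
        )
        assert list(rep.raw.index) == [2]
        assert (rep.standardized.loc[2] == 0.0).all()

    def test_unbalanced_partitions_flagged_and_excluded(self, default_cohort):
        rep = wt.criterion_sweep(
            default_cohort.matrix, range(2, 7), restarts=5, rng_seed=1
        )
        floor = 0.10 * 96
        for k, flagged in rep.unbalanced.items():
            assert flagged == (rep.sizes[k].min() < floor)
        assert not rep.unbalanced[rep.recommended_k]

    def test_report_is_well_formed_without_planted_structure(self):
        cfg = wt.CohortConfig(class_probs=(0.0, 1.0, 0.0), session_noise_sd=0.9,
                              rng_seed=5)
        cohort = wt.simulate_cohort(cfg)
        rep = wt.criterion_sweep(cohort.matrix, range(2, 5), restarts=5, rng_seed=5)
        assert rep.raw.shape == (3, 5)
        assert np.isfinite(rep.raw["ch1"]).all()
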