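"""Split-half validation of the trajectory clustering.

The cohort is split by parity of the 1-based participant enumeration
(file order).  Each half is re-clustered at the full-data k, the held-out
half is assigned to the trained seeds by nearest distance, half labels are
aligned to the full-data labels by optimal (Hungarian) matching, and
concordance — how many participants land in the same cluster as under the
full-data partition — is reported per half and combined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cluster import Partition, _pairwise_sq_dist, fit
from .io import TrajectoryMatrix

__all__ = [
    "SplitResult",
    "ConcordanceSummary",
    "split_by_parity",
    "assign_to_seeds",
    "match_labels",
    "concordance",
    "crossvalidate",
]


@dataclass
class SplitResult:
    """Outcome of training on one half and assigning the other."""

    half_id: str                       # "odd" or "even"
    train_partition: Partition
    test_assignments: dict[str, int]   # held-out participant -> raw half label
    matched_labels: dict[int, int]     # half label -> full-data label
    concordant_train: int
    concordant_test: int
    proportions: dict[int, float]      # full-label -> train-half allocation frac


@dataclass
class ConcordanceSummary:
    """Combined split-half concordance against the full-data partition."""

    n: int
    concordant: int
    fraction: float
    halves: dict[str, SplitResult]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "concordant": self.concordant,
            "fraction": self.fraction,
            "halves": {
                h: {
                    "concordant_train": r.concordant_train,
                    "concordant_test": r.concordant_test,
                    "matched_labels": {str(k): v for k, v in r.matched_labels.items()},
                    "proportions": {str(k): v for k, v in r.proportions.items()},
                }
                for h, r in self.halves.items()
            },
        }


def split_by_parity(matrix: TrajectoryMatrix, k: int = 3):
    """Split into odd- and even-numbered halves by 1-based file order.

    Returns ``(odd, even)`` as TrajectoryMatrix views; participant 1 (the
    first row) is odd.  Errors if either half is too small to cluster
    at k.
    """
    idx = np.arange(matrix.n)
    odd = matrix.subset(idx[::2])    # 1-based odd = 0-based even rows
    even = matrix.subset(idx[1::2])
    if min(odd.n, even.n) < 2 * k:
        raise ValueError(
            f"cohort of {matrix.n} too small to cluster halves at k={k}"
        )
    return odd, even


def assign_to_seeds(seeds: np.ndarray, matrix: TrajectoryMatrix) -> dict[str, int]:
    """Assign every trajectory to the nearest seed (1-based labels).

    A trajectory sharing no observed session with any seed is flagged
    unassignable (label 0).
    """
    d2 = _pairwise_sq_dist(matrix.values, seeds)
    labels = np.argmin(d2, axis=1) + 1
    labels[np.isinf(d2).all(axis=1)] = 0
    return {p: int(c) for p, c in zip(matrix.participants, labels)}


def match_labels(
    reference: dict[str, int],
    other: dict[str, int],
    k: int,
) -> dict[int, int]:
    """Permutation of ``other``'s labels maximizing agreement with ``reference``.

    Solved as an optimal assignment over the k x k contingency table of
    the participants present in both (labels 1..k; unassignable 0 entries
    are ignored).
    """
    table = np.zeros((k, k))
    for pid, lab in other.items():
        ref = reference.get(pid, 0)
        if lab > 0 and ref > 0:
            table[lab - 1, ref - 1] += 1
    rows, cols = linear_sum_assignment(-table)
    return {int(r + 1): int(c + 1) for r, c in zip(rows, cols)}


def _half_result(
    half_id: str,
    train: TrajectoryMatrix,
    test: TrajectoryMatrix,
    full: Partition,
    restarts: int,
    rng_seed: int,
    refit_test: bool,
) -> SplitResult:
    part = fit(train, full.k, restarts=restarts, rng_seed=rng_seed)
    if refit_test:
        test_part = fit(test, full.k, restarts=restarts, rng_seed=rng_seed + 1)
        test_assign = test_part.assignments
    else:
        test_assign = assign_to_seeds(part.seeds, test)

    full_assign = full.assignments
    half_assign = {**part.assignments, **test_assign}
    mapping = match_labels(full_assign, half_assign, full.k)

    conc_train = sum(
        mapping.get(lab, 0) == full_assign[pid]
        for pid, lab in part.assignments.items()
    )
    conc_test = sum(
        lab > 0 and mapping.get(lab, 0) == full_assign[pid]
        for pid, lab in test_assign.items()
    )
    sizes = part.sizes()
    proportions = {
        mapping.get(c, c): float(sizes[c - 1] / part.n) for c in range(1, full.k + 1)
    }
    return SplitResult(
        half_id=half_id,
        train_partition=part,
        test_assignments=test_assign,
        matched_labels=mapping,
        concordant_train=int(conc_train),
        concordant_test=int(conc_test),
        proportions=proportions,
    )


def concordance(full: Partition, odd: SplitResult, even: SplitResult):
    """Combined concordance count/fraction over the whole cohort.

    Every participant is counted once per half (as a train member in one
    half and a test assignee in the other); a participant is concordant
    if both half-derived clusters agree with the full-data cluster.
    """
    full_assign = full.assignments
    agree = 0
    for pid in full.participants:
        ok = True
        for res in (odd, even):
            if pid in res.train_partition.assignments:
                lab = res.train_partition.assignments[pid]
            else:
                lab = res.test_assignments.get(pid, 0)
            if lab <= 0 or res.matched_labels.get(lab, 0) != full_assign[pid]:
                ok = False
        agree += ok
    return ConcordanceSummary(
        n=full.n,
        concordant=agree,
        fraction=agree / full.n,
        halves={"odd": odd, "even": even},
    )


def crossvalidate(
    matrix: TrajectoryMatrix,
    full: Partition | None = None,
    k: int = 3,
    restarts: int = 20,
    rng_seed: int = 0,
    refit_test: bool = False,
) -> ConcordanceSummary:
    """Run the whole odd/even split-half validation.

    ``full`` is the full-data partition (fitted here if not supplied); k
    for the halves is fixed to the full-data k.
    """
    if full is None:
        full = fit(matrix, k, restarts=restarts, rng_seed=rng_seed)
    odd_m, even_m = split_by_parity(matrix, full.k)
    odd = _half_result(
        "odd", odd_m, even_m, full, restarts, rng_seed + 101, refit_test
    )
    even = _half_result(
        "even", even_m, odd_m, full, restarts, rng_seed + 202, refit_test
    )
    return concordance(full, odd, even)
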