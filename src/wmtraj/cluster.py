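"""Longitudinal k-means over variable-length training trajectories.

Implements the expectation--maximization style k-means used for clustering
learning curves: seeds (cluster-mean trajectories) are recomputed per time
point from observed values only, trajectories are reassigned to the nearest
seed, and the two phases alternate until the partition is a fixed point.
Initialization is k-means++ and the whole procedure is restarted several
times, keeping the restart with the highest Calinski-Harabasz score.

Missing sessions are handled without imputation: the distance between two
trajectories is the Euclidean distance over their jointly observed time
points inflated by sqrt(T / m), so short and long trajectories live on a
comparable scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TrajectoryMatrix

__all__ = [
    "Partition",
    "CriterionReport",
    "trajectory_distance",
    "kmeanspp_init",
    "fit_once",
    "fit",
    "calinski_harabasz",
    "ray_turi",
    "davies_bouldin",
    "criterion_sweep",
    "CRITERION_NAMES",
]

CRITERION_NAMES = ["ch1", "ch2", "ch3", "ray_turi", "davies_bouldin"]


@dataclass
class Partition:
    """A k-clustering of trajectories.

    ``labels`` are 1-based cluster indices aligned with ``participants``;
    ``seeds`` is a (k, T) grid of per-time-point means over observed member
    values (NaN where no member was observed).  Clusters are relabeled so
    that cluster 1 has the lowest overall seed level and cluster k the
    highest, which keeps labels comparable across runs.
    """

    k: int
    participants: list[str]
    labels: np.ndarray
    seeds: np.ndarray
    n: int
    rng_seed: int | None = None
    restart_index: int | None = None
    converged: bool = True
    iterations: int = 0
    criteria: dict[str, float] = field(default_factory=dict)

    @property
    def assignments(self) -> dict[str, int]:
        return {p: int(c) for p, c in zip(self.participants, self.labels)}

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def members(self, c: int) -> np.ndarray:
        """Row indices of cluster ``c`` (1-based label)."""
        return np.flatnonzero(self.labels == c)


def _pairwise_sq_dist(values: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Squared adjusted distances between every trajectory and every seed.

    Returns a (n, k) array; entries are +inf where a trajectory and a seed
    share no observed time point (incomparable).
    """
    T = values.shape[1]
    x = values[:, None, :]
    s = seeds[None, :, :]
    diff = x - s
    joint = ~np.isnan(diff)
    m = joint.sum(axis=2)
    sq = np.where(joint, np.square(np.where(joint, diff, 0.0)), 0.0).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(m > 0, (T / np.maximum(m, 1)) * sq, np.inf)
    return d2


def trajectory_distance(x: np.ndarray, y: np.ndarray, T: int | None = None) -> float:
    """Missing-data-adjusted Euclidean distance between two trajectories.

    ``sqrt(T/m) * ||x - y||`` over the m jointly observed points, where T is
    the full trajectory length.  Returns +inf when no point is jointly
    observed (the pair is incomparable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if T is None:
        T = x.size
    joint = ~(np.isnan(x) | np.isnan(y))
    m = int(joint.sum())
    if m == 0:
        return np.inf
    return float(np.sqrt((T / m) * np.sum((x[joint] - y[joint]) ** 2)))


def _canonical_order(matrix: TrajectoryMatrix) -> np.ndarray:
    # rng-driven choices are made in participant-id order so that permuting
    # file rows cannot change which trajectories get picked
    return np.argsort(np.asarray(matrix.participants, dtype=object))


def kmeanspp_init(
    matrix: TrajectoryMatrix, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding: first seed uniform, later seeds D^2-weighted.

    Returns a (k, T) array of seed trajectories copied from actual
    participants (all distinct).
    """
    n = matrix.n
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of participants ({n})")
    order = _canonical_order(matrix)
    values = matrix.values[order]

    chosen: list[int] = [int(rng.integers(n))]
    while len(chosen) < k:
        d2 = _pairwise_sq_dist(values, values[chosen])
        nearest = np.min(d2, axis=1)
        nearest[chosen] = 0.0
        finite = np.isfinite(nearest)
        weights = np.where(finite, nearest, 0.0)
        total = weights.sum()
        if total <= 0:
            # all remaining points coincide with a seed: fall back to uniform
            # over not-yet-chosen rows
            pool = np.setdiff1d(np.arange(n), chosen)
            chosen.append(int(rng.choice(pool)))
            continue
        chosen.append(int(rng.choice(n, p=weights / total)))
    return values[chosen].copy()


def _recompute_seeds(values: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    T = values.shape[1]
    seeds = np.full((k, T), np.nan)
    for c in range(1, k + 1):
        members = values[labels == c]
        if members.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            seeds[c - 1] = np.nanmean(members, axis=0)
    return seeds


def _relabel_by_level(labels: np.ndarray, seeds: np.ndarray, k: int):
    """Relabel clusters so mean seed level is ascending in the label."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        level = np.array([np.nanmean(seeds[c]) for c in range(k)])
    level = np.where(np.isnan(level), np.inf, level)
    order = np.argsort(level, kind="stable")
    new_label = np.empty(k, dtype=int)
    new_label[order] = np.arange(1, k + 1)
    return new_label[labels - 1], seeds[order]


def fit_once(
    matrix: TrajectoryMatrix,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 200,
) -> Partition:
    """One k-means++ initialized EM run to a fixed partition.

    Alternates nearest-seed assignment (ties go to the lowest cluster
    index) and per-time-point seed recomputation until no assignment
    changes or ``max_iter`` is hit.  An emptied cluster is re-seeded from
    the trajectory currently farthest from its own seed.
    """
    if not 2 <= k <= matrix.n:
        raise ValueError(f"k must lie in [2, {matrix.n}]")
    order = _canonical_order(matrix)
    values = matrix.values[order]
    n, T = values.shape

    seeds = kmeanspp_init(matrix, k, rng)
    labels = np.zeros(n, dtype=int)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        d2 = _pairwise_sq_dist(values, seeds)
        if np.isinf(d2).all(axis=1).any():
            bad = int(np.flatnonzero(np.isinf(d2).all(axis=1))[0])
            raise ValueError(
                "trajectory shares no observed session with any seed "
                f"(participant {matrix.participants[order[bad]]!r})"
            )
        new_labels = np.argmin(d2, axis=1) + 1
        # re-seed empty clusters from the currently farthest trajectory
        for c in range(1, k + 1):
            if not np.any(new_labels == c):
                assigned = d2[np.arange(n), new_labels - 1]
                far = int(np.argmax(np.where(np.isfinite(assigned), assigned, -1.0)))
                new_labels[far] = c
                seeds[c - 1] = values[far]
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        seeds = _recompute_seeds(values, labels, k)
    if not converged:
        warnings.warn(
            f"k-means did not converge within {max_iter} iterations", stacklevel=2
        )

    labels, seeds = _relabel_by_level(labels, seeds, k)
    # map back to the input participant order
    out_labels = np.empty(n, dtype=int)
    out_labels[order] = labels
    return Partition(
        k=k,
        participants=list(matrix.participants),
        labels=out_labels,
        seeds=seeds,
        n=n,
        converged=converged,
        iterations=iterations,
    )


def fit(
    matrix: TrajectoryMatrix,
    k: int,
    restarts: int = 20,
    rng_seed: int = 0,
    max_iter: int = 200,
) -> Partition:
    """Restarted longitudinal k-means.

    Runs :func:`fit_once` ``restarts`` times on independent substreams of
    ``rng_seed`` and returns the partition with the highest variant-1
    Calinski-Harabasz score (first such restart on ties, so the result is
    deterministic given the seed).
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    streams = np.random.SeedSequence(rng_seed).spawn(restarts)
    best: Partition | None = None
    best_score = -np.inf
    for r, ss in enumerate(streams):
        part = fit_once(matrix, k, np.random.default_rng(ss), max_iter=max_iter)
        score = calinski_harabasz(part, matrix, variant=1)
        if score > best_score:
            best, best_score = part, score
            best.restart_index = r
    assert best is not None
    best.rng_seed = rng_seed
    best.criteria = all_criteria(best, matrix)
    return best


def _within_between(partition: Partition, matrix: TrajectoryMatrix):
    """Trace(W), Trace(B) from adjusted squared distances."""
    values = matrix.values
    T = matrix.T
    W = 0.0
    B = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        grand = np.nanmean(values, axis=0)
    for c in range(1, partition.k + 1):
        idx = partition.members(c)
        seed = partition.seeds[c - 1]
        for i in idx:
            W += trajectory_distance(values[i], seed, T) ** 2
        B += len(idx) * trajectory_distance(seed, grand, T) ** 2
    return W, B


def calinski_harabasz(
    partition: Partition, matrix: TrajectoryMatrix, variant: int = 1
) -> float:
    """Calinski-Harabasz criterion: between/within trace ratio, df-scaled.

    variant 1 (used for model selection): (B/W) * (n-k)/(k-1)
    variant 2: (B/W) * (n-1)/(n-k)
    variant 3: the unscaled trace ratio B/W
    Higher is better for all three.
    """
    if variant not in (1, 2, 3):
        raise ValueError("variant must be 1, 2 or 3")
    n, k = partition.n, partition.k
    if k < 2:
        raise ValueError("Calinski-Harabasz requires k >= 2")
    W, B = _within_between(partition, matrix)
    if W == 0.0:
        warnings.warn("zero within-cluster scatter; criterion is infinite", stacklevel=2)
        return np.inf
    ratio = B / W
    if variant == 1:
        return ratio * (n - k) / (k - 1)
    if variant == 2:
        return ratio * (n - 1) / (n - k)
    return ratio


def ray_turi(partition: Partition, matrix: TrajectoryMatrix) -> float:
    """Negated Ray-Turi index: -(mean within scatter / min seed gap^2).

    Stored negated so that higher = better, like the other criteria.
    """
    W, _ = _within_between(partition, matrix)
    k, T = partition.k, matrix.T
    min_gap2 = np.inf
    for i in range(k):
        for j in range(i + 1, k):
            d = trajectory_distance(partition.seeds[i], partition.seeds[j], T)
            min_gap2 = min(min_gap2, d * d)
    if min_gap2 == 0.0 or not np.isfinite(min_gap2):
        warnings.warn("coincident or incomparable seeds in Ray-Turi", stacklevel=2)
        return -np.inf
    return -(W / partition.n) / min_gap2


def davies_bouldin(partition: Partition, matrix: TrajectoryMatrix) -> float:
    """Negated Davies-Bouldin index (mean worst compactness/separation ratio)."""
    k, T = partition.k, matrix.T
    values = matrix.values
    S = np.empty(k)
    for c in range(1, k + 1):
        idx = partition.members(c)
        S[c - 1] = np.mean(
            [trajectory_distance(values[i], partition.seeds[c - 1], T) for i in idx]
        )
    total = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if j == i:
                continue
            M = trajectory_distance(partition.seeds[i], partition.seeds[j], T)
            if M == 0.0 or not np.isfinite(M):
                warnings.warn(
                    "coincident or incomparable seeds in Davies-Bouldin", stacklevel=2
                )
                return -np.inf
            worst = max(worst, (S[i] + S[j]) / M)
        total += worst
    return -total / k


def all_criteria(partition: Partition, matrix: TrajectoryMatrix) -> dict[str, float]:
    return {
        "ch1": calinski_harabasz(partition, matrix, 1),
        "ch2": calinski_harabasz(partition, matrix, 2),
        "ch3": calinski_harabasz(partition, matrix, 3),
        "ray_turi": ray_turi(partition, matrix),
        "davies_bouldin": davies_bouldin(partition, matrix),
    }


@dataclass
class CriterionReport:
    """Validity criteria across a range of k, raw and standardized.

    ``raw`` and ``standardized`` are DataFrames indexed by k with one
    column per criterion (all oriented so higher = better; Ray-Turi and
    Davies-Bouldin are negated).  ``standardized`` z-scores each criterion
    across the k range.  ``unbalanced`` flags k whose smallest cluster
    falls below the size floor; ``recommended_k`` is the unflagged k with
    the best mean standardized criterion (a recommendation, not an
    automatic choice).
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame
    sizes: dict[int, np.ndarray]
    unbalanced: dict[int, bool]
    partitions: dict[int, Partition]
    recommended_k: int

    def consensus(self) -> pd.Series:
        """Mean standardized criterion per k (higher = better)."""
        return self.standardized.mean(axis=1)


def _standardize_grid(raw: pd.DataFrame) -> pd.DataFrame:
    std = raw.copy().astype(float)
    for col in std.columns:
        x = std[col].to_numpy(dtype=float)
        finite = np.isfinite(x)
        if finite.sum() < 2 or np.std(x[finite]) == 0.0:
            std[col] = np.where(finite, 0.0, x)
            continue
        mu, sd = np.mean(x[finite]), np.std(x[finite])
        std[col] = np.where(finite, (x - mu) / sd, x)
    return std


def criterion_sweep(
    matrix: TrajectoryMatrix,
    k_range=range(2, 7),
    restarts: int = 20,
    rng_seed: int = 0,
    min_cluster_frac: float = 0.10,
) -> CriterionReport:
    """Fit every k in ``k_range`` and tabulate the five validity criteria.

    Each criterion is z-scored across k; partitions whose smallest cluster
    holds fewer than ``min_cluster_frac`` of the cohort are flagged
    unbalanced and excluded from the recommendation.
    """
    k_list = sorted(set(int(k) for k in k_range))
    if not k_list or k_list[0] < 2:
        raise ValueError("k_range must contain integers >= 2")
    rows = {}
    sizes = {}
    unbalanced = {}
    partitions = {}
    floor = min_cluster_frac * matrix.n
    for k in k_list:
        part = fit(matrix, k, restarts=restarts, rng_seed=rng_seed)
        rows[k] = part.criteria
        sizes[k] = part.sizes()
        unbalanced[k] = bool(part.sizes().min() < floor)
        partitions[k] = part
    raw = pd.DataFrame.from_dict(rows, orient="index")[CRITERION_NAMES]
    raw.index.name = "k"
    standardized = _standardize_grid(raw)
    consensus = standardized.mean(axis=1)
    eligible = [k for k in k_list if not unbalanced[k]] or k_list
    recommended = max(eligible, key=lambda k: consensus.loc[k])
    return CriterionReport(
        raw=raw,
        standardized=standardized,
        sizes=sizes,
        unbalanced=unbalanced,
        partitions=partitions,
        recommended_k=int(recommended),
    )
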