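"""Between- and within-cluster inference on outcomes and predictors.

One-way ANOVAs (with eta-squared effect sizes) compare symptom-index
change scores and baseline predictors across trajectory clusters;
significant omnibus tests are followed by Tukey HSD pairwise comparisons,
with the family alpha Bonferroni-divided across the outcome indices
tested; within-cluster pre-post change is tested with paired t-tests and
Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import Partition
from .io import TrajectoryMatrix

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "PairedTResult",
    "trajectory_descriptives",
    "oneway_anova",
    "tukey_hsd",
    "paired_t",
    "predictor_screen",
    "outcome_analysis",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta2: float
    group_summaries: pd.DataFrame  # index=group, columns n/mean/sd

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
            "eta2": self.eta2,
            "groups": self.group_summaries.reset_index().to_dict("records"),
        }


@dataclass
class TukeyResult:
    pairs: pd.DataFrame  # columns: group_i, group_j, mean_diff, adjusted_p, significant
    family_alpha: float
    bonferroni_families: int

    @property
    def alpha(self) -> float:
        return self.family_alpha / self.bonferroni_families

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "pairs": self.pairs.to_dict("records"),
        }


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    cohens_d: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "cohens_d": self.cohens_d,
            "n_pairs": self.n_pairs,
        }


def _group_arrays(values: dict | pd.Series, groups: dict | pd.Series):
    """Align values with group labels, dropping missing pairs."""
    v = pd.Series(values, dtype=float)
    g = pd.Series(groups)
    common = v.index.intersection(g.index)
    v, g = v.loc[common], g.loc[common]
    keep = v.notna() & g.notna()
    v, g = v[keep], g[keep]
    out = {}
    for label in sorted(g.unique()):
        out[label] = v[g == label].to_numpy(dtype=float)
    return out


def oneway_anova(values, groups) -> AnovaResult:
    """Classic one-way between-groups ANOVA with eta-squared.

    ``values`` and ``groups`` are participant-keyed mappings/Series;
    participants with a missing value are dropped pairwise.  eta2 =
    SS_between / SS_total.
    """
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups with data")
    for label, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    all_vals = np.concatenate(list(arrays.values()))
    if np.allclose(all_vals, all_vals[0]):
        raise ValueError("outcome has zero variance")
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        F = np.inf
        p = 0.0
    else:
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    eta2 = ss_between / (ss_between + ss_within)
    summaries = pd.DataFrame(
        {
            "n": {k: a.size for k, a in arrays.items()},
            "mean": {k: a.mean() for k, a in arrays.items()},
            "sd": {k: a.std(ddof=1) for k, a in arrays.items()},
        }
    )
    summaries.index.name = "group"
    return AnovaResult(float(F), df_b, df_w, float(p), float(eta2), summaries)


def tukey_hsd(
    values,
    groups,
    family_alpha: float = 0.05,
    bonferroni_families: int = 3,
) -> TukeyResult:
    """Tukey-Kramer HSD pairwise comparisons with a Bonferroni-shrunk alpha.

    Adjusted p-values come from the studentized range distribution; a pair
    is flagged significant when adjusted p < family_alpha /
    bonferroni_families (the number of outcome indices in the testing
    family, 3 by default).
    """
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    for label, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    labels = list(arrays)
    ns = np.array([arrays[g].size for g in labels])
    means = np.array([arrays[g].mean() for g in labels])
    df_w = int(ns.sum() - len(labels))
    ms_w = sum(((arrays[g] - arrays[g].mean()) ** 2).sum() for g in labels) / df_w
    k = len(labels)
    alpha = family_alpha / bonferroni_families
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(ms_w / 2 * (1 / ns[i] + 1 / ns[j]))
            q = np.abs(diff) / se if se > 0 else np.inf
            p_adj = float(sps.studentized_range.sf(q, k, df_w)) if se > 0 else 0.0
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "mean_diff": float(diff),
                    "adjusted_p": min(max(p_adj, 0.0), 1.0),
                    "significant": bool(p_adj < alpha),
                }
            )
    return TukeyResult(pd.DataFrame(rows), family_alpha, bonferroni_families)


def paired_t(pre, post) -> PairedTResult:
    """Paired t-test on pre - post differences with Cohen's d.

    d = mean(diff) / sd(diff); pairs with either side missing are dropped.
    A positive t means scores decreased from pre to post.
    """
    pre = pd.Series(pre, dtype=float)
    post = pd.Series(post, dtype=float)
    common = pre.index.intersection(post.index)
    diff = (pre.loc[common] - post.loc[common]).dropna().to_numpy()
    if diff.size < 2:
        raise ValueError("paired t-test needs >= 2 complete pairs")
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        d = 0.0 if mean == 0 else np.inf * np.sign(mean)
    else:
        t = mean / (sd / np.sqrt(diff.size))
        p = float(2 * sps.t.sf(np.abs(t), diff.size - 1))
        d = mean / sd
    return PairedTResult(float(t), int(diff.size - 1), p, float(d), int(diff.size))


def trajectory_descriptives(
    partition: Partition, matrix: TrajectoryMatrix
) -> pd.DataFrame:
    """Per-cluster first-day score, last-day score and training improvement.

    Improvement is each participant's last observed score minus their
    first observed score, averaged within cluster.
    """
    values = matrix.values
    first = np.full(matrix.n, np.nan)
    last = np.full(matrix.n, np.nan)
    for i in range(matrix.n):
        obs = np.flatnonzero(~np.isnan(values[i]))
        first[i] = values[i, obs[0]]
        last[i] = values[i, obs[-1]]
    improvement = last - first
    rows = []
    for c in range(1, partition.k + 1):
        idx = partition.members(c)
        rows.append(
            {
                "cluster": c,
                "n": len(idx),
                "first_day_mean": first[idx].mean(),
                "first_day_sd": first[idx].std(ddof=1) if len(idx) > 1 else np.nan,
                "last_day_mean": last[idx].mean(),
                "last_day_sd": last[idx].std(ddof=1) if len(idx) > 1 else np.nan,
                "improvement_mean": improvement[idx].mean(),
                "improvement_sd": improvement[idx].std(ddof=1)
                if len(idx) > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


@dataclass
class PredictorScreen:
    """Table of per-predictor cluster ANOVAs (Table-2 style report)."""

    anovas: dict[str, AnovaResult]
    tukeys: dict[str, TukeyResult] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for name, a in self.anovas.items():
            rows.append(
                {
                    "predictor": name,
                    "F": a.F,
                    "df_between": a.df_between,
                    "df_within": a.df_within,
                    "p": a.p,
                    "eta2": a.eta2,
                    "significant": a.p < 0.05,
                }
            )
        return pd.DataFrame(rows).set_index("predictor")


def predictor_screen(
    partition: Partition,
    baseline: pd.DataFrame,
    predictors: list[str] | None = None,
    alpha: float = 0.05,
) -> PredictorScreen:
    """One ANOVA per baseline predictor against cluster membership.

    Gender enters numerically coded.  No multiple-testing correction is
    applied at this exploratory stage; Tukey follow-ups are computed only
    for predictors whose omnibus test is significant at ``alpha``.
    """
    groups = partition.assignments
    if predictors is None:
        predictors = [
            c for c in baseline.columns if c not in ("study_id",) and
            pd.api.types.is_numeric_dtype(baseline[c])
        ]
    anovas: dict[str, AnovaResult] = {}
    tukeys: dict[str, TukeyResult] = {}
    for name in predictors:
        values = baseline[name]
        anovas[name] = oneway_anova(values, groups)
        if anovas[name].p < alpha:
            # exploratory screen: no Bonferroni shrinkage here
            tukeys[name] = tukey_hsd(values, groups, bonferroni_families=1)
    return PredictorScreen(anovas=anovas, tukeys=tukeys)


def outcome_analysis(
    partition: Partition,
    index_table: pd.DataFrame,
    outcomes: tuple[str, ...] = ("anxiety_change", "depression_change", "general_change"),
    family_alpha: float = 0.05,
) -> dict:
    """ANOVA + Tukey + per-cluster paired t for each change-score outcome.

    The Tukey family alpha is Bonferroni-divided by the number of
    outcomes.  Per-cluster paired t-tests compare pre vs post index
    values in each cluster for outcomes whose omnibus ANOVA is
    significant.
    """
    groups = pd.Series(partition.assignments)
    report: dict[str, dict] = {}
    for outcome in outcomes:
        if outcome not in index_table.columns:
            continue
        values = index_table[outcome]
        entry: dict = {}
        anova = oneway_anova(values, groups)
        entry["anova"] = anova
        entry["tukey"] = tukey_hsd(
            values, groups, family_alpha, bonferroni_families=len(outcomes)
        )
        if anova.p < family_alpha:
            base = outcome.replace("_change_followup", "").replace("_change", "")
            tp = "followup" if outcome.endswith("_followup") else "post"
            pre_col, post_col = f"{base}_pre", f"{base}_{tp}"
            if pre_col in index_table.columns and post_col in index_table.columns:
                ttests = {}
                for c in range(1, partition.k + 1):
                    members = [
                        p for p, lab in partition.assignments.items()
                        if lab == c and p in index_table.index
                    ]
                    sub = index_table.loc[members]
                    complete = sub[[pre_col, post_col]].dropna()
                    if len(complete) >= 2:
                        ttests[c] = paired_t(complete[pre_col], complete[post_col])
                entry["paired_t"] = ttests
        report[outcome] = entry
    return report
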