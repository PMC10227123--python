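"""Composite psychological symptom indices from heterogeneous questionnaires.

Different source studies administered different instruments; to pool them,
each raw total is z-standardized against a per-instrument reference norm
(by default the cohort's pooled pre-training mean/SD) and averaged into
three composite indices:

* anxiety   = mean of available z(STAI), z(PSWQ), z(SAS2)
* depression = mean of available z(BDI), z(RRS)
* general   = mean of anxiety and depression (or whichever exists)

All five instruments score higher = worse, so the improvement (change)
score is pre minus post: positive means symptom reduction.  Post and
follow-up scores are standardized against the *pre* norms so change is
measured on a fixed scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ANXIETY_INSTRUMENTS",
    "DEPRESSION_INSTRUMENTS",
    "TIMEPOINTS",
    "IndexScores",
    "cohort_norms",
    "build_indices",
    "build_index_table",
]

ANXIETY_INSTRUMENTS = ("STAI", "PSWQ", "SAS2")
DEPRESSION_INSTRUMENTS = ("BDI", "RRS")
KNOWN_INSTRUMENTS = ANXIETY_INSTRUMENTS + DEPRESSION_INSTRUMENTS
TIMEPOINTS = ("pre", "post", "followup")


@dataclass
class IndexScores:
    """Composite indices and improvement scores for one participant."""

    participant_id: str
    anxiety: dict[str, float]      # timepoint -> index (missing key = missing)
    depression: dict[str, float]
    general: dict[str, float]
    improvements: dict[str, float]  # e.g. anxiety_change, anxiety_change_followup

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {"participant_id": self.participant_id}
        for name, d in (
            ("anxiety", self.anxiety),
            ("depression", self.depression),
            ("general", self.general),
        ):
            for tp in TIMEPOINTS:
                row[f"{name}_{tp}"] = d.get(tp, np.nan)
        for key in (
            "anxiety_change",
            "depression_change",
            "general_change",
            "anxiety_change_followup",
            "depression_change_followup",
            "general_change_followup",
        ):
            row[key] = self.improvements.get(key, np.nan)
        return row


def _validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "timepoint", "instrument", "score"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    bad_tp = set(panel["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    dup = panel.duplicated(subset=["participant_id", "timepoint", "instrument"])
    if dup.any():
        r = panel.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate entry: participant {r.participant_id!r}, "
            f"{r.instrument} at {r.timepoint}"
        )
    return panel


def cohort_norms(panel: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-instrument (mean, sd) of pre-training raw scores across the cohort.

    These are the default standardization reference for
    :func:`build_indices`.  SD uses ddof=1; an instrument observed fewer
    than twice pre-training, or with zero variance, is an error.
    """
    panel = _validate_panel(panel)
    pre = panel[panel["timepoint"] == "pre"]
    norms: dict[str, tuple[float, float]] = {}
    for inst, grp in pre.groupby("instrument"):
        scores = grp["score"].dropna().to_numpy(dtype=float)
        if scores.size < 2:
            raise ValueError(
                f"instrument {inst!r}: need >= 2 pre-training observations"
            )
        sd = float(np.std(scores, ddof=1))
        if sd == 0.0:
            raise ValueError(f"instrument {inst!r} has zero pre-training variance")
        norms[str(inst)] = (float(np.mean(scores)), sd)
    return norms


def _composite(z: Mapping[tuple[str, str], float], instruments, tp: str):
    vals = [z[(inst, tp)] for inst in instruments if (inst, tp) in z]
    return float(np.mean(vals)) if vals else None


def build_indices(
    panel: pd.DataFrame,
    norms: Mapping[str, tuple[float, float]],
) -> IndexScores:
    """Build the three composite indices for one participant's panel.

    Raises if an instrument in the panel lacks a norm.  Improvements are
    defined only where both pre and post (or follow-up) index values
    exist; a one-sided panel yields missing improvements, not an error.
    """
    panel = _validate_panel(panel)
    pids = panel["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("build_indices expects a single participant's panel")
    pid = str(pids[0])

    z: dict[tuple[str, str], float] = {}
    for r in panel.itertuples(index=False):
        if r.instrument not in norms:
            raise ValueError(f"no norm for instrument {r.instrument!r}")
        mu, sd = norms[r.instrument]
        if sd <= 0:
            raise ValueError(f"instrument {r.instrument!r}: norm sd must be > 0")
        z[(r.instrument, r.timepoint)] = (float(r.score) - mu) / sd

    anxiety, depression, general = {}, {}, {}
    for tp in TIMEPOINTS:
        a = _composite(z, ANXIETY_INSTRUMENTS, tp)
        d = _composite(z, DEPRESSION_INSTRUMENTS, tp)
        if a is not None:
            anxiety[tp] = a
        if d is not None:
            depression[tp] = d
        avail = [v for v in (a, d) if v is not None]
        if avail:
            general[tp] = float(np.mean(avail))

    improvements: dict[str, float] = {}
    for name, series in (
        ("anxiety", anxiety),
        ("depression", depression),
        ("general", general),
    ):
        if "pre" in series and "post" in series:
            improvements[f"{name}_change"] = series["pre"] - series["post"]
        if "pre" in series and "followup" in series:
            improvements[f"{name}_change_followup"] = (
                series["pre"] - series["followup"]
            )
    return IndexScores(pid, anxiety, depression, general, improvements)


def build_index_table(
    panel: pd.DataFrame,
    norms: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Indices for every participant in a long panel, as one wide table.

    ``norms`` defaults to :func:`cohort_norms` of the panel itself.
    Returns a DataFrame indexed by participant_id with 9 index columns
    (3 indices x 3 timepoints) and 6 change columns.
    """
    panel = _validate_panel(panel)
    if norms is None:
        norms = cohort_norms(panel)
    rows = [
        build_indices(grp, norms).as_row()
        for _, grp in panel.groupby("participant_id", sort=False)
    ]
    return pd.DataFrame(rows).set_index("participant_id")
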