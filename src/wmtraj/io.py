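"""Reading and writing the tidy CSV formats consumed by the pipeline.

The central in-memory container is :class:`TrajectoryMatrix`, a participants
x sessions grid of daily adaptive n-back scores (NaN where a session was not
observed).  Trajectories of unequal length are padded to the cohort maximum,
never imputed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_MIN = 1.0
SCORE_MAX = 4.0

#: minimum observed sessions for a trajectory to be clusterable
MIN_OBSERVED_SESSIONS = 3

DEFAULT_SCHEMA = {
    "participant_id": "participant_id",
    "study_id": "study_id",
    "session": "session",
    "score": "score",
}


@dataclass
class TrajectoryMatrix:
    """Aligned per-participant training trajectories.

    Attributes
    ----------
    participants : list of str
        Participant identifiers in first-appearance order.
    values : ndarray, shape (n, T)
        Daily scores; ``NaN`` marks unobserved sessions.  Column ``t``
        holds session ``t + 1`` (sessions are reported 1-based).
    study_of : dict
        Maps participant id to study id.
    """

    participants: list[str]
    values: np.ndarray
    study_of: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.participants)

    @property
    def T(self) -> int:
        return self.values.shape[1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.participants):
            raise ValueError("values must be a (n_participants, T) array")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (obs.min() < SCORE_MIN or obs.max() > SCORE_MAX):
            raise ValueError(
                f"observed scores must lie in [{SCORE_MIN}, {SCORE_MAX}]"
            )

    def index_of(self, participant_id: str) -> int:
        return self.participants.index(participant_id)

    def subset(self, idx: Sequence[int]) -> "TrajectoryMatrix":
        """Row subset preserving order of ``idx``."""
        idx = list(idx)
        parts = [self.participants[i] for i in idx]
        return TrajectoryMatrix(
            participants=parts,
            values=self.values[idx].copy(),
            study_of={p: self.study_of.get(p, "") for p in parts},
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format frame with one row per observed (participant, session)."""
        rows = []
        for i, pid in enumerate(self.participants):
            obs = np.flatnonzero(~np.isnan(self.values[i]))
            for t in obs:
                rows.append(
                    (pid, self.study_of.get(pid, ""), t + 1, self.values[i, t])
                )
        return pd.DataFrame(
            rows, columns=["participant_id", "study_id", "session", "score"]
        )


def read_training_log(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    min_sessions: int = MIN_OBSERVED_SESSIONS,
) -> TrajectoryMatrix:
    """Read a long-format training log CSV into a :class:`TrajectoryMatrix`.

    Parameters
    ----------
    path : path
        CSV with columns participant_id, study_id, session, score
        (renameable through ``schema``).  Unobserved sessions are absent
        rows or empty score cells.
    schema : mapping, optional
        Maps canonical column names to the file's column names.

    Raises
    ------
    ValueError
        On duplicate (participant, session) rows or out-of-range scores.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    missing_cols = [c for c in schema.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"training log missing columns: {missing_cols}")
    df = df.rename(columns={v: k for k, v in schema.items()})
    df = df.dropna(subset=["score"])
    df["participant_id"] = df["participant_id"].astype(str)
    df["session"] = df["session"].astype(int)

    if (df["session"] < 1).any():
        bad = df.loc[df["session"] < 1].iloc[0]
        raise ValueError(f"session index must be >= 1 (participant {bad.participant_id})")
    dup = df.duplicated(subset=["participant_id", "session"], keep=False)
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(
            "duplicate (participant, session) row: "
            f"participant {bad.participant_id!r}, session {int(bad.session)}"
        )
    out_of_range = (df["score"] < SCORE_MIN) | (df["score"] > SCORE_MAX)
    if out_of_range.any():
        bad = df.loc[out_of_range].iloc[0]
        raise ValueError(
            f"score {bad.score} outside [{SCORE_MIN}, {SCORE_MAX}] "
            f"(participant {bad.participant_id!r}, session {int(bad.session)})"
        )

    order = df["participant_id"].drop_duplicates().tolist()
    T = int(df["session"].max())
    values = np.full((len(order), T), np.nan)
    study_of: dict[str, str] = {}
    for i, pid in enumerate(order):
        sub = df[df["participant_id"] == pid]
        values[i, sub["session"].to_numpy() - 1] = sub["score"].to_numpy()
        study_of[pid] = str(sub["study_id"].iloc[0])

    n_obs = (~np.isnan(values)).sum(axis=1)
    keep = n_obs >= min_sessions
    if not keep.all():
        dropped = [order[i] for i in np.flatnonzero(~keep)]
        msg = (
            f"excluded {len(dropped)} participant(s) with fewer than "
            f"{min_sessions} observed sessions: {dropped}"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    kept = [order[i] for i in np.flatnonzero(keep)]
    return TrajectoryMatrix(
        participants=kept,
        values=values[keep],
        study_of={p: study_of[p] for p in kept},
    )


def write_partition(partition, path: str | Path) -> None:
    """Write a fitted partition as CSV plus a JSON metadata sidecar.

    The CSV holds ``participant_id,cluster`` (labels 1..k).  The sidecar
    (same path with ``.json`` suffix) records k, seed trajectories,
    criterion scores, restart index and RNG seed so that a published run
    can be reproduced exactly.
    """
    if getattr(partition, "assignments", None) is None:
        raise ValueError("cannot write an unfitted partition")
    path = Path(path)
    df = pd.DataFrame(
        {
            "participant_id": partition.participants,
            "cluster": [int(partition.assignments[p]) for p in partition.participants],
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "k": int(partition.k),
        "seeds": [
            [None if np.isnan(v) else float(v) for v in seed]
            for seed in partition.seeds
        ],
        "criteria": {k: float(v) for k, v in (partition.criteria or {}).items()},
        "rng_seed": partition.rng_seed,
        "restart_index": partition.restart_index,
        "converged": bool(partition.converged),
        "iterations": int(partition.iterations),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_partition(path: str | Path) -> tuple[dict[str, int], dict]:
    """Read back a partition CSV + sidecar; returns (assignments, metadata)."""
    path = Path(path)
    df = pd.read_csv(path)
    assignments = {
        str(r.participant_id): int(r.cluster) for r in df.itertuples(index=False)
    }
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return assignments, meta


def read_questionnaires(path: str | Path) -> pd.DataFrame:
    """Read the questionnaire panel CSV (participant_id,timepoint,instrument,score)."""
    df = pd.read_csv(path)
    required = {"participant_id", "timepoint", "instrument", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"questionnaire CSV missing columns: {sorted(missing)}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def read_baseline(path: str | Path) -> pd.DataFrame:
    """Read the baseline table CSV (participant_id plus predictor columns)."""
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError("baseline CSV must contain participant_id")
    df["participant_id"] = df["participant_id"].astype(str)
    return df.set_index("participant_id")
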