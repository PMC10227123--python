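"""Synthetic cohort generator with planted learner classes.

Emulates a 96-participant, six-study adaptive dual n-back training cohort:
three latent learner classes (non-learners with a mid-training hump, steady
linear learners, and fast saturating learners), study-specific training
durations and questionnaire batteries, early-truncation dropout, and
baseline cognition / anxiety-change outcomes that differ by class.  The
planted class of every participant is stored for recovery testing only and
is never read by the inference modules.

Daily scores are the mean adaptive n-back level, bounded in [1, 4]; class
templates are parametric curves through the anchor levels that each learner
type reaches at the start, middle and end of training, with additive
Gaussian session noise clipped back into range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TrajectoryMatrix

__all__ = [
    "StudyDesign",
    "ClassOutcomeParams",
    "CohortConfig",
    "SyntheticCohort",
    "generate_trajectory",
    "generate_outcomes",
    "simulate_cohort",
    "DEFAULT_STUDIES",
    "INSTRUMENT_NORMS",
]

SCORE_MIN, SCORE_MAX = 1.0, 4.0

#: fixed reference norms used to map index-scale values onto raw
#: questionnaire totals (plausible scale locations; the analysis is
#: invariant to them because indices re-standardize against cohort norms)
INSTRUMENT_NORMS = {
    "STAI": (45.0, 10.0),
    "PSWQ": (55.0, 12.0),
    "SAS2": (30.0, 8.0),
    "BDI": (15.0, 8.0),
    "RRS": (45.0, 12.0),
}

ANXIETY_INSTRUMENTS = ("STAI", "PSWQ", "SAS2")
DEPRESSION_INSTRUMENTS = ("BDI", "RRS")


@dataclass(frozen=True)
class StudyDesign:
    """One source study: size, training duration and assessment battery."""

    study_id: str
    n: int
    duration: int
    instruments: tuple[str, ...]
    cognitive_tasks: tuple[str, ...]  # subset of {"cdt", "flanker"}
    age_mean: float
    age_sd: float
    female_frac: float
    followup: bool = False


# Six-study cohort layout: sizes, durations, instrument panels, follow-up
# availability and demographics mirror a multi-study WM-training pool
# (96 participants, durations 7-15 sessions, dropout 8-20%).
DEFAULT_STUDIES: tuple[StudyDesign, ...] = (
    StudyDesign("owens", 11, 8, ("BDI",), ("cdt",), 25.27, 5.33, 7 / 11),
    StudyDesign("sari", 13, 15, ("STAI", "PSWQ"), ("flanker",), 22.81, 4.47, 8 / 13),
    StudyDesign(
        "hotton", 20, 15, ("PSWQ", "STAI"), ("cdt", "flanker"), 29.2, 11.75,
        16 / 20, followup=True,
    ),
    StudyDesign("ducrocq", 13, 10, ("SAS2",), ("cdt",), 34.77, 13.29, 3 / 13),
    StudyDesign(
        "wiener", 24, 14, ("STAI", "BDI", "PSWQ", "RRS"), ("cdt", "flanker"),
        25.92, 3.53, 6 / 24, followup=True,
    ),
    StudyDesign(
        "course_choi", 15, 7, ("STAI", "PSWQ", "RRS"), ("cdt",), 27.93, 7.29,
        10 / 15, followup=True,
    ),
)


@dataclass(frozen=True)
class ClassOutcomeParams:
    """Per-class (mean, sd) for each class-linked outcome or baseline."""

    anxiety_change: tuple[tuple[float, float], ...] = (
        (-0.208, 0.513),  # non-learners: anxiety worsens slightly
        (0.0, 0.50),      # steady learners: no net change (interpolated)
        (0.193, 0.478),   # saturating learners: anxiety improves
    )
    anxiety_change_followup: tuple[tuple[float, float], ...] = (
        (-0.270, 0.825),
        (0.05, 0.60),     # interpolated between the printed extremes
        (0.380, 0.431),
    )
    # depression change carries no class effect
    depression_change: tuple[float, float] = (0.0, 0.50)
    cdt_pre: tuple[tuple[float, float], ...] = (
        (1.03, 1.09),
        (1.38, 0.8327),   # mid class: interpolated mean, pooled sd
        (1.73, 0.447),
    )
    flanker_pre: tuple[tuple[float, float], ...] = (
        (79.0, 32.7),
        (78.4, 35.7),
        (41.2, 28.1),     # lower interference = better inhibition
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the study conditions."""

    n_participants: int = 96
    class_probs: tuple[float, float, float] = (0.312, 0.375, 0.313)
    session_noise_sd: float = 0.45
    studies: tuple[StudyDesign, ...] = DEFAULT_STUDIES
    dropout_range: tuple[float, float] = (0.08, 0.20)
    outcome_params: ClassOutcomeParams = field(default_factory=ClassOutcomeParams)
    instrument_noise_sd: float = 0.15
    study_baseline_shift: float = 0.0  # optional per-study index shift (sd units)
    rng_seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_probs) - 1.0) > 1e-6:
            raise ValueError("class_probs must sum to 1")
        if any(p < 0 for p in self.class_probs):
            raise ValueError("class_probs must be non-negative")
        if self.session_noise_sd < 0:
            raise ValueError("session_noise_sd must be >= 0")
        if sum(s.n for s in self.studies) != self.n_participants:
            raise ValueError(
                "study sizes must sum to n_participants "
                f"({sum(s.n for s in self.studies)} != {self.n_participants})"
            )
        for s in self.studies:
            if not 7 <= s.duration <= 15:
                raise ValueError(f"study {s.study_id}: duration must lie in [7, 15]")
        lo, hi = self.dropout_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("dropout_range must satisfy 0 <= lo <= hi < 1")


# ---------------------------------------------------------------------------
# trajectory templates

# anchors: (session, mean level)
_C1_ANCHORS = ((1.0, 1.39), (8.0, 1.76), (15.0, 1.28))  # hump, no net learning
_C2_START, _C2_END = 1.86, 3.34                          # linear improvement
_C3_START, _C3_END, _C3_CEIL = 2.46, 3.70, 4.0           # saturating curve

# quadratic through the three class-1 anchors
_C1_COEF = np.polyfit([a[0] for a in _C1_ANCHORS], [a[1] for a in _C1_ANCHORS], 2)
# class-3 rate so the curve passes 3.70 at session 15 with asymptote 4
_C3_RATE = np.log((_C3_CEIL - _C3_START) / (_C3_CEIL - _C3_END)) / 14.0


def class_template(class_id: int, sessions: np.ndarray) -> np.ndarray:
    """Noise-free mean trajectory of a learner class at 1-based sessions."""
    s = np.asarray(sessions, dtype=float)
    if class_id == 1:
        return np.polyval(_C1_COEF, s)
    if class_id == 2:
        return _C2_START + (_C2_END - _C2_START) * (s - 1.0) / 14.0
    if class_id == 3:
        return _C3_CEIL - (_C3_CEIL - _C3_START) * np.exp(-_C3_RATE * (s - 1.0))
    raise ValueError(f"unknown learner class {class_id!r}")


def generate_trajectory(
    class_id: int,
    duration: int,
    rng: np.random.Generator,
    noise_sd: float = 0.45,
) -> np.ndarray:
    """Draw one training trajectory: class template + session noise, clipped.

    ``duration`` is the number of training days (7-15); the returned vector
    holds sessions 1..duration.
    """
    if not 7 <= duration <= 15:
        raise ValueError("duration must lie in [7, 15]")
    sessions = np.arange(1, duration + 1)
    mean = class_template(class_id, sessions)
    traj = mean + rng.normal(0.0, noise_sd, size=duration)
    return np.clip(traj, SCORE_MIN, SCORE_MAX)


def generate_outcomes(
    class_id: int,
    rng: np.random.Generator,
    params: ClassOutcomeParams | None = None,
) -> dict[str, float]:
    """Draw class-linked outcomes and baselines for one participant.

    Returns anxiety/depression pre-post change on the index scale, the
    follow-up anxiety change, and baseline CDT (working-memory capacity)
    and flanker interference scores.  Depression change is class
    independent by design.
    """
    params = params or ClassOutcomeParams()
    if class_id not in (1, 2, 3):
        raise ValueError(f"unknown learner class {class_id!r}")
    c = class_id - 1
    draw = lambda ms: rng.normal(ms[0], ms[1])
    return {
        "anxiety_change": draw(params.anxiety_change[c]),
        "depression_change": draw(params.depression_change),
        "anxiety_change_followup": draw(params.anxiety_change_followup[c]),
        "depression_change_followup": draw(params.depression_change),
        "cdt_pre": draw(params.cdt_pre[c]),
        "flanker_pre": draw(params.flanker_pre[c]),
    }


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its ground truth.

    ``true_class`` exists for recovery testing only; inference modules
    must never read it.
    """

    matrix: TrajectoryMatrix
    true_class: dict[str, int]
    panels: pd.DataFrame      # participant_id, timepoint, instrument, score
    baseline: pd.DataFrame    # participant_id, study_id, age, gender, cdt_pre, flanker_pre
    latent: pd.DataFrame      # planted index-scale changes (testing only)
    config: CohortConfig

    def write_csvs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "training": outdir / "training.csv",
            "questionnaires": outdir / "questionnaires.csv",
            "baseline": outdir / "baseline.csv",
            "truth": outdir / "truth.csv",
        }
        self.matrix.to_long().to_csv(paths["training"], index=False)
        self.panels.to_csv(paths["questionnaires"], index=False)
        self.baseline.to_csv(paths["baseline"], index=False)
        pd.DataFrame(
            {
                "participant_id": list(self.true_class),
                "true_class": list(self.true_class.values()),
            }
        ).to_csv(paths["truth"], index=False)
        return paths


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Simulate a full cohort under ``config`` (reproducible given rng_seed).

    Learner classes are i.i.d. from ``class_probs``; training duration
    comes from the participant's study, with a random subset (dropout
    fraction drawn uniformly from ``dropout_range``) truncated early.
    Questionnaire raw totals are back-constructed from index-scale latent
    values through fixed reference norms, so that indices rebuilt by the
    analysis carry the configured per-class change distributions.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.rng_seed)
    p = np.asarray(config.class_probs, dtype=float)
    p = p / p.sum()

    pids, study_of, durations = [], {}, {}
    for study in config.studies:
        for _ in range(study.n):
            pid = f"p{len(pids) + 1:03d}"
            pids.append(pid)
            study_of[pid] = study.study_id
            durations[pid] = study.duration
    n = len(pids)
    study_by_id = {s.study_id: s for s in config.studies}

    classes = rng.choice([1, 2, 3], size=n, p=p)

    # dropout: early truncation of a random subset
    frac = rng.uniform(*config.dropout_range)
    n_drop = int(round(frac * n))
    drop_idx = rng.choice(n, size=n_drop, replace=False)
    for i in drop_idx:
        pid = pids[i]
        durations[pid] = int(rng.integers(3, study_by_id[study_of[pid]].duration))

    T = max(s.duration for s in config.studies)
    values = np.full((n, T), np.nan)
    for i, pid in enumerate(pids):
        # dropout truncates the study-length trajectory early
        full = generate_trajectory(
            classes[i],
            study_by_id[study_of[pid]].duration,
            rng,
            config.session_noise_sd,
        )
        d = durations[pid]
        values[i, :d] = full[:d]

    panel_rows, base_rows, latent_rows = [], [], []
    shift_sd = config.study_baseline_shift
    study_shift = {
        s.study_id: (rng.normal(0.0, shift_sd) if shift_sd > 0 else 0.0)
        for s in config.studies
    }
    for i, pid in enumerate(pids):
        study = study_by_id[study_of[pid]]
        out = generate_outcomes(classes[i], rng, config.outcome_params)
        anx_pre = rng.normal(0.0, 1.0) + study_shift[study.study_id]
        dep_pre = rng.normal(0.0, 1.0) + study_shift[study.study_id]
        index_at = {
            "pre": {"anxiety": anx_pre, "depression": dep_pre},
            "post": {
                "anxiety": anx_pre - out["anxiety_change"],
                "depression": dep_pre - out["depression_change"],
            },
        }
        if study.followup:
            index_at["followup"] = {
                "anxiety": anx_pre - out["anxiety_change_followup"],
                "depression": dep_pre - out["depression_change_followup"],
            }
        for timepoint, idx in index_at.items():
            for inst in study.instruments:
                domain = "anxiety" if inst in ANXIETY_INSTRUMENTS else "depression"
                mu, sd = INSTRUMENT_NORMS[inst]
                raw = mu + sd * (
                    idx[domain] + rng.normal(0.0, config.instrument_noise_sd)
                )
                panel_rows.append((pid, timepoint, inst, raw))
        base_rows.append(
            (
                pid,
                study.study_id,
                float(np.clip(rng.normal(study.age_mean, study.age_sd), 18.0, 75.0)),
                int(rng.random() < study.female_frac),
                out["cdt_pre"] if "cdt" in study.cognitive_tasks else np.nan,
                out["flanker_pre"] if "flanker" in study.cognitive_tasks else np.nan,
            )
        )
        latent_rows.append(
            (
                pid,
                int(classes[i]),
                out["anxiety_change"],
                out["depression_change"],
                out["anxiety_change_followup"] if study.followup else np.nan,
            )
        )

    matrix = TrajectoryMatrix(participants=pids, values=values, study_of=study_of)
    panels = pd.DataFrame(
        panel_rows, columns=["participant_id", "timepoint", "instrument", "score"]
    )
    baseline = pd.DataFrame(
        base_rows,
        columns=["participant_id", "study_id", "age", "gender", "cdt_pre", "flanker_pre"],
    )
    latent = pd.DataFrame(
        latent_rows,
        columns=[
            "participant_id",
            "true_class",
            "anxiety_change",
            "depression_change",
            "anxiety_change_followup",
        ],
    )
    return SyntheticCohort(
        matrix=matrix,
        true_class={pid: int(c) for pid, c in zip(pids, classes)},
        panels=panels,
        baseline=baseline,
        latent=latent,
        config=config,
    )


def config_with_seed(config: CohortConfig | None, rng_seed: int) -> CohortConfig:
    """Copy of ``config`` (or the defaults) with the given seed."""
    return replace(config or CohortConfig(), rng_seed=rng_seed)
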