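"""Synthetic per-mouse behavioral datasets with the model's generative structure.

Emulates the deposited behavioral data of the object-memory study:
independent groups of mice tested once each at retention intervals of
24 hr, 1, 2 or 3 weeks (between-subjects), each mouse contributing one
familiar-object exploration probability drawn from the model's Beta
observation distribution at its test day.  Defaults: 12 mice per group
(figure legends report n = 4-12), 30 s total exploration when raw times
are attached.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engram_model import ModelParams, beta_shape, exploration_mean, run_trajectory
from .task_model import STANDARD_TEST_DAYS, TaskSchedule

__all__ = [
    "MU_CLIP",
    "DEFAULT_N_MICE",
    "DEFAULT_TOTAL_TIME_S",
    "ExplorationObservation",
    "generate_group",
    "generate_forgetting_curve_dataset",
    "attach_raw_times",
    "observations_to_frame",
    "frame_to_observations",
    "write_csv",
    "read_csv",
]

#: Observed probabilities are clipped to this open interval: the Beta
#: log-density is degenerate at the boundaries for shapes > 1.
MU_CLIP = 1e-4

DEFAULT_N_MICE = 12
DEFAULT_TOTAL_TIME_S = 30.0

CSV_COLUMNS = [
    "subject_id",
    "condition",
    "test_day",
    "time_novel_s",
    "time_familiar_s",
    "mu_hat",
]


@dataclass(frozen=True)
class ExplorationObservation:
    """One mouse's familiar-object exploration probability at its test day."""

    subject_id: str
    condition: str
    test_day: int
    mu_hat: float
    time_novel: float | None = None
    time_familiar: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.mu_hat < 1.0:
            raise ValueError(f"mu_hat must lie in (0, 1), got {self.mu_hat}")
        if self.time_novel is not None and self.time_familiar is not None:
            total = self.time_novel + self.time_familiar
            if total <= 0:
                raise ValueError("total exploration time must be positive")
            if abs(self.time_familiar / total - self.mu_hat) > 1e-9:
                raise ValueError("raw times inconsistent with mu_hat")


def _clip(mu: np.ndarray | float) -> np.ndarray | float:
    return np.clip(mu, MU_CLIP, 1.0 - MU_CLIP)


def generative_mu(params: ModelParams, schedule: TaskSchedule) -> float:
    """Model mean exploration probability at the schedule's test day."""
    traj = run_trajectory(schedule, params)
    return float(_clip(exploration_mean(traj.test_day_relevancy, 0.0, params.beta)))


def generate_group(
    params: ModelParams,
    schedule: TaskSchedule,
    n_mice: int = DEFAULT_N_MICE,
    seed: int | np.random.Generator = 0,
    subject_prefix: str = "m",
) -> list[ExplorationObservation]:
    """Simulate one group of mice tested at the schedule's test day.

    Each mouse's observed probability is one draw from
    Beta(mu*kappa, (1-mu)*kappa), with mu from the learning + exploration
    model; draws are clipped away from {0, 1}.  Deterministic given seed.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = generative_mu(params, schedule)
    a, b = beta_shape(mu, params.kappa)
    draws = _clip(rng.beta(a, b, size=n_mice))
    return [
        ExplorationObservation(
            subject_id=f"{subject_prefix}{schedule.test_day:02d}_{i:03d}",
            condition=schedule.condition_name,
            test_day=schedule.test_day,
            mu_hat=float(d),
        )
        for i, d in enumerate(draws)
    ]


def generate_forgetting_curve_dataset(
    params: ModelParams,
    schedules: Sequence[TaskSchedule] | None = None,
    test_days: Sequence[int] = STANDARD_TEST_DAYS,
    n_mice_per_day: int = DEFAULT_N_MICE,
    seed: int = 0,
    condition: str = "standard",
) -> list[ExplorationObservation]:
    """Between-subjects forgetting-curve dataset: one fresh group per test day.

    Either pass explicit ``schedules`` (one per group) or ``test_days``
    plus a ``condition`` label for plain no-reminder schedules.
    """
    if schedules is None:
        from .task_model import build_schedule

        schedules = [build_schedule(condition, d) for d in test_days]
    rng = np.random.default_rng(seed)
    out: list[ExplorationObservation] = []
    for sched in schedules:
        out.extend(generate_group(params, sched, n_mice_per_day, rng))
    return out


def attach_raw_times(
    observations: Iterable[ExplorationObservation],
    total_time: float = DEFAULT_TOTAL_TIME_S,
    seed: int | None = None,
    jitter_sd: float = 0.0,
) -> list[ExplorationObservation]:
    """Derive per-object exploration times consistent with each mu_hat.

    By default every mouse gets the same total; with ``jitter_sd`` > 0 the
    totals are log-normally jittered (seeded) to emulate variable overall
    exploration drive.  Either way mu_hat is exactly recoverable from the
    attached times.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for obs in observations:
        tot = total_time
        if jitter_sd > 0:
            tot = float(total_time * rng.lognormal(0.0, jitter_sd))
        out.append(
            replace(
                obs,
                time_familiar=obs.mu_hat * tot,
                time_novel=(1.0 - obs.mu_hat) * tot,
            )
        )
    return out


# -- tabular I/O (CSV schema shared with behavior_metrics) -----------------


def observations_to_frame(observations: Sequence[ExplorationObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [o.subject_id for o in observations],
            "condition": [o.condition for o in observations],
            "test_day": [o.test_day for o in observations],
            "time_novel_s": [o.time_novel for o in observations],
            "time_familiar_s": [o.time_familiar for o in observations],
            "mu_hat": [o.mu_hat for o in observations],
        }
    )


def frame_to_observations(df: pd.DataFrame) -> list[ExplorationObservation]:
    missing = [c for c in ("subject_id", "condition", "test_day", "mu_hat") if c not in df]
    if missing:
        raise ValueError(f"behavioral table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        tn = getattr(row, "time_novel_s", None)
        tf = getattr(row, "time_familiar_s", None)
        out.append(
            ExplorationObservation(
                subject_id=str(row.subject_id),
                condition=str(row.condition),
                test_day=int(row.test_day),
                mu_hat=float(row.mu_hat),
                time_novel=None if tn is None or pd.isna(tn) else float(tn),
                time_familiar=None if tf is None or pd.isna(tf) else float(tf),
            )
        )
    return out


def write_csv(
    observations: Sequence[ExplorationObservation],
    path,
    header_comment: str | None = None,
) -> None:
    df = observations_to_frame(observations)
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_csv(path) -> list[ExplorationObservation]:
    return frame_to_observations(pd.read_csv(path, comment="#"))
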