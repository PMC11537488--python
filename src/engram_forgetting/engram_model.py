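"""Engram-relevancy learning model and exploration observation model.

A single latent state, the engram relevancy ``e_t`` in [0, 1], tracks the
strength of the object-context association for the familiar object.  It is
updated daily by a Rescorla-Wagner delta rule with asymmetric learning
rates: presence of the object (non-negative prediction error) updates at
rate 1, absence (negative prediction error) decays at the fitted rate
``alpha_neg``:

    e_{t+1} = e_t + alpha_t * (o_t - e_t),   alpha_t = 1 if delta_t >= 0
                                                       alpha_neg otherwise

A softmax over the relevancies of the familiar and novel object (the novel
object's relevancy is fixed at 0) maps the memory state to the mean
familiar-object exploration probability mu, and a Beta distribution with
concentration kappa (shapes a = mu*kappa, b = (1-mu)*kappa) models the
across-mouse variability of the observed probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .task_model import TaskSchedule

__all__ = [
    "ModelParams",
    "EngramTrajectory",
    "FIT_BOUNDS",
    "prediction_error",
    "select_learning_rate",
    "update_relevancy",
    "run_trajectory",
    "exploration_mean",
    "beta_shape",
    "sample_exploration",
]

#: Fitting bounds for the three free parameters (alpha_neg, beta, kappa).
FIT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_neg": (0.0, 0.25),
    "beta": (-10.0, 0.0),
    "kappa": (1.0, 100.0),
}


class DegenerateShapeError(ValueError):
    """Beta shapes would be zero (mu exactly 0 or 1)."""


@dataclass(frozen=True)
class ModelParams:
    """Learning and observation parameters.

    ``alpha_neg`` is the learning rate for negative prediction errors (the
    forgetting speed); ``alpha_pos`` is fixed at 1 (one presence event fully
    restores relevancy).  ``beta`` is the softmax inverse temperature
    (negative values encode novelty preference), ``kappa`` the Beta
    concentration (larger = less across-mouse variability) and ``e_init``
    the relevancy before acquisition (0 for a never-experienced object).

    Simulation presets may set ``alpha_neg`` above the 0.25 fitting bound
    (e.g. 0.5 for the context-only / Rac1-activation conditions); the
    bounds in :data:`FIT_BOUNDS` constrain estimation only.
    """

    alpha_neg: float
    beta: float = -5.0
    kappa: float = 10.0
    alpha_pos: float = 1.0
    e_init: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_neg <= 1.0:
            raise ValueError(f"alpha_neg must be in [0, 1], got {self.alpha_neg}")
        if not 0.0 <= self.alpha_pos <= 1.0:
            raise ValueError(f"alpha_pos must be in [0, 1], got {self.alpha_pos}")
        if not 0.0 <= self.e_init <= 1.0:
            raise ValueError(f"e_init must be in [0, 1], got {self.e_init}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")

    def within_fit_bounds(self) -> bool:
        lo_a, hi_a = FIT_BOUNDS["alpha_neg"]
        lo_b, hi_b = FIT_BOUNDS["beta"]
        lo_k, hi_k = FIT_BOUNDS["kappa"]
        return (
            lo_a <= self.alpha_neg <= hi_a
            and lo_b <= self.beta <= hi_b
            and lo_k <= self.kappa <= hi_k
        )

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def prediction_error(o: float, e: float) -> float:
    """delta = o - e, the daily prediction error."""
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"relevancy must be in [0, 1], got {e}")
    return o - e


def select_learning_rate(delta: float, params: ModelParams) -> float:
    """Asymmetric rate: alpha_pos (=1) for delta >= 0, alpha_neg otherwise."""
    return params.alpha_pos if delta >= 0 else params.alpha_neg


def update_relevancy(e: float, o: int, params: ModelParams) -> float:
    """One delta-rule step e' = e + alpha * (o - e)."""
    delta = prediction_error(o, e)
    return e + select_learning_rate(delta, params) * delta


@dataclass(frozen=True)
class EngramTrajectory:
    """Daily relevancies and prediction errors over one schedule.

    ``relevancy[t]`` is the relevancy ENTERING day t (before that day's
    update), for t = 0..T+1; ``prediction_error[t]`` is delta_t for
    t = 0..T.  Test-day behavior is read from the relevancy entering the
    test day, i.e. before the test exposure itself updates the engram.
    """

    relevancy: tuple[float, ...]
    prediction_error: tuple[float, ...]
    schedule: TaskSchedule
    params: ModelParams = field(compare=False)

    def relevancy_entering(self, day: int) -> float:
        return self.relevancy[day]

    @property
    def test_day_relevancy(self) -> float:
        return self.relevancy[self.schedule.test_day]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-day table: day, object_presence, relevancy, prediction_error."""
        T = self.schedule.horizon_T
        return pd.DataFrame(
            {
                "day": np.arange(T + 1),
                "object_presence": self.schedule.object_presence,
                "relevancy": self.relevancy[: T + 1],
                "prediction_error": self.prediction_error,
                "condition": self.schedule.condition_name,
            }
        )


def run_trajectory(schedule: TaskSchedule, params: ModelParams) -> EngramTrajectory:
    """Iterate the delta rule over the schedule's full day grid.

    Starts from ``params.e_init`` entering day 0 and applies one update per
    day t = 0..T, so the sequence of relevancies has length T+2.
    """
    e = params.e_init
    relevancies = [e]
    deltas = []
    for o in schedule.object_presence:
        d = prediction_error(o, e)
        deltas.append(d)
        e = e + select_learning_rate(d, params) * d
        relevancies.append(e)
    return EngramTrajectory(
        relevancy=tuple(relevancies),
        prediction_error=tuple(deltas),
        schedule=schedule,
        params=params,
    )


def exploration_mean(
    e_familiar: float | np.ndarray,
    e_novel: float | np.ndarray = 0.0,
    beta: float = -5.0,
) -> float | np.ndarray:
    """Softmax mean exploration probability for the familiar object.

    mu = exp(beta*e_familiar) / (exp(beta*e_familiar) + exp(beta*e_novel)).
    Equal relevancies give exactly 0.5 for any beta.  Computed with
    max-subtraction for stability (harmless here, but standard practice).
    """
    zf = np.multiply(beta, e_familiar)
    zn = np.multiply(beta, e_novel)
    m = np.maximum(zf, zn)
    ef = np.exp(zf - m)
    en = np.exp(zn - m)
    out = ef / (ef + en)
    return float(out) if np.ndim(out) == 0 else out


def beta_shape(mu: float, kappa: float) -> tuple[float, float]:
    """Beta shapes a = mu*kappa, b = (1-mu)*kappa; a + b = kappa."""
    if not 0.0 < mu < 1.0:
        raise DegenerateShapeError(f"mu must lie strictly in (0, 1), got {mu}")
    return mu * kappa, (1.0 - mu) * kappa


def sample_exploration(
    mu: float,
    kappa: float,
    seed: int | np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw observed exploration probabilities from Beta(mu*kappa, (1-mu)*kappa)."""
    a, b = beta_shape(mu, kappa)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draw = rng.beta(a, b, size=size)
    return float(draw) if size is None else draw


def relevancy_closed_form(test_day: int, alpha_neg: float) -> float:
    """Closed-form relevancy entering the test day for a reminder-free schedule.

    With acquisition at day 0 (one full positive update to 1) and d-1
    absence days, the relevancy entering test day d is (1 - alpha_neg)^(d-1).
    Used as an independent oracle for :func:`run_trajectory`.
    """
    return (1.0 - alpha_neg) ** (test_day - 1)


def trajectories_frame(
    schedules: Sequence[TaskSchedule], params: ModelParams
) -> pd.DataFrame:
    """Concatenated tidy trajectories for several schedules."""
    return pd.concat(
        [run_trajectory(s, params).to_frame() for s in schedules], ignore_index=True
    )
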