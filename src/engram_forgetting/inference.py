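"""Maximum-likelihood fitting, BIC model comparison and parameter recovery.

Three free parameters are estimated jointly per experimental group: the
negative-prediction-error learning rate alpha_neg, the softmax inverse
temperature beta and the Beta concentration kappa (alpha_pos = 1 and
e_init = 0 stay fixed).  The group log-likelihood sums, over mice, the
Beta log-density of each observed exploration probability at the model's
test-day shapes:

    l = sum_s log Beta(mu_hat_s ; a_s, b_s)

Optimization is bound-constrained L-BFGS-B (bounds [0, 0.25] for
alpha_neg, [-10, 0] for beta, [1, 100] for kappa) with seeded uniform
multi-starts, since the likelihood can be flat in kappa at small group
sizes.  Model comparison uses the criterion

    BIC = l - (k/2) * ln(S)

(k free parameters, S subjects) where HIGHER is better; the chance
baseline (mu = 0.5, Beta shapes a = b = 1, k = 0) has l = 0 and BIC = 0
on any dataset, so a positive fitted BIC means the learning model beats
chance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .engram_model import FIT_BOUNDS, ModelParams, exploration_mean, run_trajectory
from .synthetic_data import (
    MU_CLIP,
    ExplorationObservation,
    generate_forgetting_curve_dataset,
)
from .task_model import STANDARD_TEST_DAYS, TaskSchedule, build_schedule

__all__ = [
    "FitError",
    "FitResult",
    "RecoveryReport",
    "beta_log_density",
    "group_log_likelihood",
    "fit_group",
    "bic",
    "baseline_fit",
    "compare_to_baseline",
    "parameter_recovery",
    "DEFAULT_N_STARTS",
]

DEFAULT_N_STARTS = 10

#: Free parameters fitted per group, in optimizer order.
FREE_PARAMS = ("alpha_neg", "beta", "kappa")


class FitError(RuntimeError):
    """No optimizer start converged."""


def beta_log_density(mu_hat, a, b):
    """Log Beta density log[ mu^(a-1) (1-mu)^(b-1) / B(a,b) ] at mu_hat.

    Vectorized over all arguments.  mu_hat must lie strictly in (0, 1)
    (callers clip); shapes must be positive.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(mu_hat <= 0.0) or np.any(mu_hat >= 1.0):
        raise ValueError("mu_hat must lie strictly in (0, 1)")
    if np.any(a <= 0.0) or np.any(b <= 0.0):
        raise ValueError("Beta shapes must be positive")
    out = (a - 1.0) * np.log(mu_hat) + (b - 1.0) * np.log1p(-mu_hat) - special.betaln(a, b)
    return float(out) if out.ndim == 0 else out


def _resolve_schedules(
    observations: Sequence[ExplorationObservation],
    schedules: Mapping[int, TaskSchedule] | Sequence[TaskSchedule] | None,
) -> dict[int, TaskSchedule]:
    """Map each observed test day to its schedule (plain schedules by default)."""
    if schedules is None:
        sched_map: dict[int, TaskSchedule] = {}
    elif isinstance(schedules, Mapping):
        sched_map = dict(schedules)
    else:
        sched_map = {s.test_day: s for s in schedules}
    for obs in observations:
        if obs.test_day not in sched_map:
            sched_map[obs.test_day] = build_schedule(obs.condition, obs.test_day)
    return sched_map


def _test_day_mus(
    days: np.ndarray, sched_map: Mapping[int, TaskSchedule], params: ModelParams
) -> np.ndarray:
    """Model mu for each observation, via one trajectory per unique test day."""
    mu_by_day = {
        d: exploration_mean(
            run_trajectory(sched_map[d], params).test_day_relevancy, 0.0, params.beta
        )
        for d in np.unique(days)
    }
    mus = np.array([mu_by_day[d] for d in days])
    return np.clip(mus, MU_CLIP, 1.0 - MU_CLIP)


def group_log_likelihood(
    observations: Sequence[ExplorationObservation],
    params: ModelParams,
    schedules: Mapping[int, TaskSchedule] | Sequence[TaskSchedule] | None = None,
) -> float:
    """Summed Beta log-likelihood of the observed probabilities under the model."""
    if len(observations) == 0:
        raise ValueError("need at least one observation")
    sched_map = _resolve_schedules(observations, schedules)
    days = np.array([o.test_day for o in observations])
    mu_hat = np.clip([o.mu_hat for o in observations], MU_CLIP, 1.0 - MU_CLIP)
    mus = _test_day_mus(days, sched_map, params)
    return float(np.sum(beta_log_density(mu_hat, mus * params.kappa, (1.0 - mus) * params.kappa)))


def bic(l: float, k: int, S: int) -> float:
    """Penalized fit criterion l - (k/2)·ln(S); higher is better."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return l - 0.5 * k * math.log(S)


@dataclass(frozen=True)
class FitResult:
    """Best-of-starts maximum-likelihood fit for one group."""

    params_hat: ModelParams
    log_likelihood: float
    n_params: int
    n_subjects: int
    bic: float
    n_starts: int
    converged: bool
    start_values: tuple[tuple[float, float, float], ...] = field(repr=False)
    start_log_likelihoods: tuple[float, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "params_hat": {
                "alpha_neg": self.params_hat.alpha_neg,
                "beta": self.params_hat.beta,
                "kappa": self.params_hat.kappa,
            },
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "n_subjects": self.n_subjects,
            "bic": self.bic,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "start_values": [list(s) for s in self.start_values],
            "start_log_likelihoods": list(self.start_log_likelihoods),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def fit_group(
    observations: Sequence[ExplorationObservation],
    schedules: Mapping[int, TaskSchedule] | Sequence[TaskSchedule] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    base_params: ModelParams | None = None,
) -> FitResult:
    """Bounded ML estimation of (alpha_neg, beta, kappa) for one group.

    Runs L-BFGS-B from ``n_starts`` uniform random starts inside the
    bounds (seeded) and keeps the best converged start; exact likelihood
    ties are broken toward smaller alpha_neg, then smaller \\|beta\\|, so the
    result is deterministic for fixed data, seed and n_starts.
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 subjects to fit a group")
    bounds = dict(FIT_BOUNDS) if bounds is None else dict(bounds)
    base = base_params or ModelParams(alpha_neg=0.0)
    sched_map = _resolve_schedules(observations, schedules)
    days = np.array([o.test_day for o in observations])
    mu_hat = np.clip([o.mu_hat for o in observations], MU_CLIP, 1.0 - MU_CLIP)
    log_mu = np.log(mu_hat)
    log_1m = np.log1p(-mu_hat)

    def neg_ll(theta: np.ndarray) -> float:
        p = base.replace(alpha_neg=theta[0], beta=theta[1], kappa=theta[2])
        mus = _test_day_mus(days, sched_map, p)
        a = mus * p.kappa
        b = (1.0 - mus) * p.kappa
        return -float(np.sum((a - 1.0) * log_mu + (b - 1.0) * log_1m - special.betaln(a, b)))

    rng = np.random.default_rng(seed)
    bound_list = [bounds[name] for name in FREE_PARAMS]
    starts = [
        tuple(rng.uniform(lo, hi) for lo, hi in bound_list) for _ in range(n_starts)
    ]

    candidates: list[tuple[np.ndarray, float]] = []
    start_lls: list[float] = []
    for x0 in starts:
        res = optimize.minimize(
            neg_ll, np.array(x0), method="L-BFGS-B", bounds=bound_list,
            options={"ftol": 1e-8, "gtol": 1e-8},
        )
        start_lls.append(-float(res.fun))
        if res.success or np.isfinite(res.fun):
            candidates.append((res.x, -float(res.fun)))
    if not candidates:
        raise FitError(f"all {n_starts} optimizer starts failed; starts={starts}")

    best_ll = max(ll for _, ll in candidates)
    tied = [x for x, ll in candidates if ll >= best_ll - 1e-9]
    x_best = min(tied, key=lambda x: (x[0], abs(x[1])))

    params_hat = base.replace(
        alpha_neg=float(x_best[0]), beta=float(x_best[1]), kappa=float(x_best[2])
    )
    ll = group_log_likelihood(observations, params_hat, sched_map)
    S = len(observations)
    k = len(FREE_PARAMS)
    return FitResult(
        params_hat=params_hat,
        log_likelihood=ll,
        n_params=k,
        n_subjects=S,
        bic=bic(ll, k, S),
        n_starts=n_starts,
        converged=True,
        start_values=tuple(starts),
        start_log_likelihoods=tuple(start_lls),
    )


def baseline_fit(observations: Sequence[ExplorationObservation]) -> FitResult:
    """Chance baseline: mu = 0.5, Beta(1, 1), no free parameters.

    The uniform density is 1 at every observation, so l = 0 and BIC = 0
    regardless of the data.
    """
    if len(observations) == 0:
        raise ValueError("need at least one observation")
    mu_hat = np.clip([o.mu_hat for o in observations], MU_CLIP, 1.0 - MU_CLIP)
    ll = float(np.sum(beta_log_density(mu_hat, 1.0, 1.0)))
    S = len(observations)
    return FitResult(
        params_hat=ModelParams(alpha_neg=0.0, beta=0.0, kappa=2.0),
        log_likelihood=ll,
        n_params=0,
        n_subjects=S,
        bic=bic(ll, 0, S),
        n_starts=0,
        converged=True,
        start_values=(),
    )


def compare_to_baseline(
    fit: FitResult, observations: Sequence[ExplorationObservation]
) -> dict:
    """Compare a fitted learning model with the chance baseline by BIC."""
    base = baseline_fit(observations)
    delta = fit.bic - base.bic
    return {
        "model_bic": fit.bic,
        "baseline_bic": base.bic,
        "delta_bic": delta,
        "winner": "learning_model" if delta > 0 else "baseline",
    }


@dataclass(frozen=True)
class RecoveryReport:
    """Simulate-and-refit summary for one generative parameter set."""

    true_params: ModelParams
    recovered: tuple[ModelParams, ...]
    bias: dict[str, float]
    rmse: dict[str, float]
    n_replicates: int
    seed: int
    n_failures: int = 0
    replicate_bics: tuple[float, ...] = ()
    baseline_win_fraction: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "replicate": i,
                "alpha_neg_hat": p.alpha_neg,
                "beta_hat": p.beta,
                "kappa_hat": p.kappa,
                "bic": self.replicate_bics[i] if self.replicate_bics else float("nan"),
            }
            for i, p in enumerate(self.recovered)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "true": {k: getattr(self.true_params, k) for k in FREE_PARAMS},
            "mean": {
                k: float(np.mean([getattr(p, k) for p in self.recovered]))
                for k in FREE_PARAMS
            },
            "bias": self.bias,
            "rmse": self.rmse,
            "n_replicates": self.n_replicates,
            "n_failures": self.n_failures,
            "model_beats_baseline_fraction": self.baseline_win_fraction,
            "seed": self.seed,
        }


def parameter_recovery(
    true_params: ModelParams,
    test_days: Sequence[int] = STANDARD_TEST_DAYS,
    n_mice_per_day: int = 12,
    n_replicates: int = 20,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
    condition: str = "recovery",
    schedules: Sequence[TaskSchedule] | None = None,
) -> RecoveryReport:
    """Generate-and-refit validation of parameter estimability.

    Each replicate simulates a fresh between-subjects dataset under
    ``true_params`` and refits; failures are recorded, not fatal.  Child
    seeds are spawned from ``seed`` so replicates are independent but the
    whole report is reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    recovered: list[ModelParams] = []
    bics: list[float] = []
    failures = 0
    for i, child in enumerate(children):
        data_seed, fit_seed = (int(s) for s in child.generate_state(2) % (2**31))
        obs = generate_forgetting_curve_dataset(
            true_params,
            schedules=schedules,
            test_days=test_days,
            n_mice_per_day=n_mice_per_day,
            seed=data_seed,
            condition=condition,
        )
        try:
            fit = fit_group(obs, schedules=schedules, n_starts=n_starts, seed=fit_seed)
        except FitError:
            failures += 1
            continue
        recovered.append(fit.params_hat)
        bics.append(fit.bic)
    if not recovered:
        raise FitError("every recovery replicate failed to fit")

    errors = {
        k: np.array([getattr(p, k) - getattr(true_params, k) for p in recovered])
        for k in FREE_PARAMS
    }
    return RecoveryReport(
        true_params=true_params,
        recovered=tuple(recovered),
        bias={k: float(np.mean(v)) for k, v in errors.items()},
        rmse={k: float(np.sqrt(np.mean(v**2))) for k, v in errors.items()},
        n_replicates=n_replicates,
        seed=seed,
        n_failures=failures,
        replicate_bics=tuple(bics),
        baseline_win_fraction=float(np.mean(np.array(bics) > 0.0)),
    )
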