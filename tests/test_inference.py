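import math

import numpy as np
import pytest
from scipy import stats

from engram_forgetting.engram_model import FIT_BOUNDS, ModelParams
from engram_forgetting.inference import (
    baseline_fit,
    beta_log_density,
    bic,
    compare_to_baseline,
    fit_group,
    group_log_likelihood,
    parameter_recovery,
)
from engram_forgetting.synthetic_data import (
    ExplorationObservation,
    generate_forgetting_curve_dataset,
)


def _obs(mu_hat, day=1, cond="c", sid="m"):
    return ExplorationObservation(sid, cond, day, mu_hat)


# -- Beta log-density -----------------------------------------------------


def test_uniform_beta_density_is_one_everywhere():
    for mu in (0.01, 0.3, 0.5, 0.97):
        assert beta_log_density(mu, 1.0, 1.0) == pytest.approx(0.0)


def test_beta_log_density_hand_value_and_symmetry():
    assert beta_log_density(0.5, 2, 2) == pytest.approx(math.log(1.5))
    assert beta_log_density(0.3, 2.5, 7.0) == pytest.approx(beta_log_density(0.7, 7.0, 2.5))


@pytest.mark.parametrize("mu", [0.0, 1.0, -0.1, 1.1])
def test_beta_log_density_rejects_boundary_observations(mu):
    with pytest.raises(ValueError):
        beta_log_density(mu, 2.0, 2.0)


def test_beta_log_density_rejects_nonpositive_shapes():
    with pytest.raises(ValueError):
        beta_log_density(0.5, 0.0, 1.0)


def test_beta_log_density_agrees_with_scipy():
    rng = np.random.default_rng(0)
    mus = rng.uniform(0.01, 0.99, 50)
    a = rng.uniform(0.1, 20, 50)
    b = rng.uniform(0.1, 20, 50)
    np.testing.assert_allclose(
        beta_log_density(mus, a, b), stats.beta.logpdf(mus, a, b), rtol=1e-10
    )


# -- group likelihood -----------------------------------------------------


def test_baseline_parameterization_gives_zero_log_likelihood(standard_dataset):
    base = baseline_fit(standard_dataset)
    assert base.log_likelihood == 0.0
    assert base.bic == 0.0
    assert base.n_params == 0


def test_group_log_likelihood_is_additive(standard_params, standard_dataset):
    half = len(standard_dataset) // 2
    a, b = standard_dataset[:half], standard_dataset[half:]
    total = group_log_likelihood(standard_dataset, standard_params)
    assert total == pytest.approx(
        group_log_likelihood(a, standard_params) + group_log_likelihood(b, standard_params)
    )


def test_single_subject_reduces_to_beta_log_density():
    # beta = 0 makes mu = 0.5; kappa = 4 gives shapes (2, 2)
    params = ModelParams(alpha_neg=0.1, beta=0.0, kappa=4.0)
    ll = group_log_likelihood([_obs(0.5)], params)
    assert ll == pytest.approx(math.log(1.5))


def test_empty_group_raises():
    with pytest.raises(ValueError):
        group_log_likelihood([], ModelParams(0.1))


# -- BIC ------------------------------------------------------------------


@pytest.mark.parametrize(
    "l, k, S, expected",
    [
        (0.0, 0, 12, 0.0),
        (-10.0, 3, 12, -10.0 - 1.5 * math.log(12)),
        (4.2, 0, 7, 4.2),
    ],
)
def test_bic_is_log_likelihood_minus_half_k_log_S(l, k, S, expected):
    assert bic(l, k, S) == pytest.approx(expected)


def test_bic_rejects_invalid_counts():
    with pytest.raises(ValueError):
        bic(0.0, 3, 0)
    with pytest.raises(ValueError):
        bic(0.0, -1, 5)


# -- fitting --------------------------------------------------------------


def test_fit_result_satisfies_bic_identity_and_bounds(standard_dataset):
    fit = fit_group(standard_dataset, seed=0)
    assert fit.bic == pytest.approx(
        fit.log_likelihood - fit.n_params / 2 * math.log(fit.n_subjects)
    )
    p = fit.params_hat
    assert FIT_BOUNDS["alpha_neg"][0] <= p.alpha_neg <= FIT_BOUNDS["alpha_neg"][1]
    assert FIT_BOUNDS["beta"][0] <= p.beta <= FIT_BOUNDS["beta"][1]
    assert FIT_BOUNDS["kappa"][0] <= p.kappa <= FIT_BOUNDS["kappa"][1]
    assert fit.n_subjects == len(standard_dataset)
    assert fit.n_params == 3


def test_fit_keeps_best_of_starts(standard_dataset):
    fit = fit_group(standard_dataset, seed=0)
    assert len(fit.start_values) == fit.n_starts == 10
    assert fit.log_likelihood >= max(fit.start_log_likelihoods) - 1e-6


def test_fit_is_deterministic_for_fixed_seed(standard_dataset):
    a = fit_group(standard_dataset, seed=5)
    b = fit_group(standard_dataset, seed=5)
    assert a.params_hat == b.params_hat
    assert a.log_likelihood == b.log_likelihood


def test_fit_requires_two_subjects():
    with pytest.raises(ValueError):
        fit_group([_obs(0.3)], seed=0)


def test_generative_parameters_beat_perturbed_ones(standard_params):
    obs = generate_forgetting_curve_dataset(standard_params, n_mice_per_day=300, seed=3)
    ll_true = group_log_likelihood(obs, standard_params)
    for perturbed in [
        standard_params.replace(alpha_neg=0.25),
        standard_params.replace(beta=-0.5),
        standard_params.replace(kappa=90.0),
    ]:
        assert ll_true > group_log_likelihood(obs, perturbed)


def test_fitted_model_beats_chance_on_model_generated_data(standard_dataset):
    fit = fit_group(standard_dataset, seed=1)
    cmp = compare_to_baseline(fit, standard_dataset)
    assert cmp["baseline_bic"] == 0.0
    assert cmp["delta_bic"] == pytest.approx(fit.bic)
    assert cmp["winner"] == "learning_model"


def test_comparison_prefers_baseline_when_fit_is_poor(standard_dataset):
    fit = fit_group(standard_dataset, seed=1)
    worse = type(fit)(
        params_hat=fit.params_hat,
        log_likelihood=-1.0,
        n_params=3,
        n_subjects=fit.n_subjects,
        bic=-1.0 - 1.5 * math.log(fit.n_subjects),
        n_starts=fit.n_starts,
        converged=True,
        start_values=fit.start_values,
    )
    assert compare_to_baseline(worse, standard_dataset)["winner"] == "baseline"


# -- recovery -------------------------------------------------------------


def test_recovery_report_invariants(standard_params):
    report = parameter_recovery(standard_params, n_replicates=4, seed=11)
    assert report.n_replicates == 4
    for name in ("alpha_neg", "beta", "kappa"):
        assert report.rmse[name] >= abs(report.bias[name])
    df = report.to_frame()
    assert len(df) == 4
    lo, hi = FIT_BOUNDS["alpha_neg"]
    assert df["alpha_neg_hat"].between(lo, hi).all()


def test_recovery_is_reproducible(standard_params):
    a = parameter_recovery(standard_params, n_replicates=3, seed=2)
    b = parameter_recovery(standard_params, n_replicates=3, seed=2)
    assert a.recovered == b.recovered


def test_zero_rate_recovers_at_lower_bound():
    report = parameter_recovery(ModelParams(alpha_neg=0.0), n_replicates=5, seed=4)
    assert np.mean([p.alpha_neg for p in report.recovered]) <= 0.01
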