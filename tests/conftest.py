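import pytest

from engram_forgetting import ModelParams, build_schedule, generate_forgetting_curve_dataset


@pytest.fixture
def standard_params():
    """Generative parameters of the standard-housing condition."""
    return ModelParams(alpha_neg=0.07, beta=-5.0, kappa=10.0)


@pytest.fixture
def day14_schedule():
    return build_schedule("standard", test_day=14)


@pytest.fixture
def standard_dataset(standard_params):
    """4 groups x 12 mice at days 1, 7, 14, 21 (between-subjects)."""
    return generate_forgetting_curve_dataset(standard_params, seed=42)
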