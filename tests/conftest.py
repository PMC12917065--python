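import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale cohort: 3 subjects/arm on a 4 x 3 mm window."""
    from tilspatial.simulate import SyntheticTruth

    return SyntheticTruth(
        n_naive=3, n_nat=3, window_mm=(4.0, 3.0), kappa_per_mm2=2.0,
        mu_offspring=50.0,
    )


@pytest.fixture(scope="session")
def pipeline_truth():
    """Cohort big enough for the full covariate-adjusted models."""
    from tilspatial.simulate import SyntheticTruth

    return SyntheticTruth(
        n_naive=8, n_nat=8, window_mm=(4.0, 3.0), kappa_per_mm2=2.0,
        mu_offspring=50.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    from tilspatial.simulate import simulate_cohort

    return simulate_cohort(small_truth, seed=11)
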