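import pytest
from hypothesis import HealthCheck, settings

import costsim as cs

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gamma_data():
    """A moderate gamma-family dataset shared across fitting tests."""
    return cs.simulate_dataset(600, "gamma", seed=101)


@pytest.fixture(scope="session")
def small_grid():
    """A cheap model grid for harness plumbing tests."""
    return cs.default_model_grid(rf_ntree=25, rf_tune_ntree=15)
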