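import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """One moderate synthetic cohort shared across recovery tests."""
    from chdyn.synthetic import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_patients=40, seed=20240611))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
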