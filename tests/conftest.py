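import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_sim():
    """A small simulated cohort shared across tests (seeded)."""
    from lohkit.synthetic_data import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(seed=11, n_patients=20))
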