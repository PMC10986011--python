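import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240402)


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort shared by structural tests."""
    from bldm.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_blocks=30,
        n_differential=8,
        delta=0.3,
        n_discovery=(20, 18),
        n_validation=(14, 12),
        n_test=(0, 0),
        seed=7,
    )
    return simulate_cohort(cfg)
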