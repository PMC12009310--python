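import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_screen():
    """One 4-plate batch, 2 replicates, no planted effects, fixed seed."""
    from ciliascreen import SimulationConfig, simulate_screen

    return simulate_screen(SimulationConfig(n_batches=1, seed=42))


@pytest.fixture(scope="session")
def small_screen_z(small_screen):
    from ciliascreen.screen import zscore_table

    return zscore_table(small_screen)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
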