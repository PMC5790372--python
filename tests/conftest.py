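import numpy as np
import pytest

from speechtrack.simulate import SimulationConfig, SimulationContext


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Desk-scale study: 2 conditions, 20 trials, 32 sensors, 2 cm grid."""
    return SimulationConfig(
        n_trials_per_condition=20,
        n_subjects_per_group={"EB": 3, "SI": 3},
        conditions=("nat", "1ch"),
        n_sensors=32,
        grid_spacing=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_ctx(tiny_config) -> SimulationContext:
    return SimulationContext(tiny_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
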