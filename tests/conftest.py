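import pytest

from bindkit import SimulationConfig


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(seed=1, noise_sd_rel=0.0)


@pytest.fixture
def noisy_config() -> SimulationConfig:
    return SimulationConfig(seed=7, noise_sd_rel=0.02)
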