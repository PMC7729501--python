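"""Shared fixtures: small, fast simulation/detection configurations."""

import numpy as np
import pytest

from qdstem import DetectionConfig, SimulationConfig


@pytest.fixture
def det_config() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def quiet_sim_config() -> SimulationConfig:
    """Noise- and texture-free simulation: geometry checks only."""
    return SimulationConfig(
        texture_amplitude=0.0,
        noise_gain=0.0,
        seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231108)
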