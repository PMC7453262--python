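"""Shared fixtures: scaled-down acquisition geometries for fast tests.

The small sensor keeps the full processing chain intact (780-pixel-style
spectral axis replaced by 130 pixels, still mapped onto the 500-channel
1-nm grid and binned to 100 channels) while making full scans cheap.
"""

import numpy as np
import pytest

from pushbroom.scanner_sim import AcquisitionConfig, SensorModel
from pushbroom.spectral_core import default_calibration


def make_small_config(**overrides) -> AcquisitionConfig:
    sensor_kwargs = {
        "n_spatial": 64,
        "n_spectral": 130,
        "read_noise_sigma": overrides.pop("read_noise_sigma", 0.0),
    }
    defaults = dict(
        n_lines=24,
        sensor=SensorModel(**sensor_kwargs),
        calibration=default_calibration(130),
        seed=overrides.pop("seed", 7),
    )
    defaults.update(overrides)
    return AcquisitionConfig(**defaults)


@pytest.fixture
def small_config() -> AcquisitionConfig:
    """Noise-free 24-line scan on a 64 x 130 sensor."""
    return make_small_config()


@pytest.fixture
def small_noisy_config() -> AcquisitionConfig:
    return make_small_config(read_noise_sigma=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
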