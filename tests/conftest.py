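import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paesim import DemodConfig, OpticalModel, ScanGeometry, SensorSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def spec() -> SensorSpec:
    return SensorSpec()


@pytest.fixture
def quiet_spec() -> SensorSpec:
    return SensorSpec().quiet()


@pytest.fixture
def demod_cfg() -> DemodConfig:
    # 50 MHz IF with the image-rejecting 35 MHz cutoff, at 250 MS/s
    return DemodConfig.for_carrier(50e6)


@pytest.fixture
def optical() -> OpticalModel:
    return OpticalModel()


@pytest.fixture
def small_raster() -> ScanGeometry:
    return ScanGeometry(mode="raster", raster_range=(0.8e-3, 0.8e-3),
                        raster_pixels=(40, 40))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
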