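import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctiq.io_formats import ImageVolume
from ctiq.synthetic import NoiseModel, make_phantom

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SPACING = (2.5, 0.5, 0.5)


@pytest.fixture(scope="session")
def white_phantom():
    """Uniform phantom with exact-variance white noise, sigma=10 HU."""
    model = NoiseModel(sigma=10.0, shape="white", seed=42)
    return make_phantom((5, 256, 256), SPACING, 0.0, model)


@pytest.fixture(scope="session")
def shaped_phantom():
    """Uniform phantom with band-pass ('fbp-like') noise peaking at 0.15 mm^-1."""
    model = NoiseModel(sigma=8.0, shape="fbp_like", params={"f0": 0.15}, seed=7)
    return make_phantom((5, 256, 256), SPACING, 0.0, model)


@pytest.fixture
def flat_volume():
    return ImageVolume(np.full((3, 64, 64), 56.0), SPACING, "flat")
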