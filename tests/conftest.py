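import numpy as np
import pytest
from hypothesis import settings

from sfxprep import BeamGeometry
from sfxprep.synthetic import simple_geometry

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_geom():
    """64x64 single-panel geometry, 100 um pixels, beam at the centre."""
    return simple_geometry((64, 64), pixel_size=1e-4)


@pytest.fixture
def beam():
    """1 A photons, 100 mm detector distance."""
    return BeamGeometry(wavelength=1.0, detector_distance=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
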