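import numpy as np
import pytest

from edred.geometry import Geometry
from edred.synthdata import make_ground_truth, simulate_pattern


@pytest.fixture(scope="session")
def geom():
    """Compact still camera: 512 px, 55 um pitch, 1.5 m, 200 kV."""
    return Geometry(camera_length=1500.0, pixel_size=0.055, wavelength=0.0251,
                    detector_shape=(512, 512))


@pytest.fixture(scope="session")
def truth(geom):
    """Small reference ground truth (3 crystals, clean detector)."""
    return make_ground_truth(geometry=geom, n_crystals=3, seed=1,
                             dead_fraction=0.0)


@pytest.fixture(scope="session")
def clean_pattern(truth, geom):
    """One noiseless pattern and its true peaks."""
    return simulate_pattern(truth, 0, 0, geom, noise=False)


@pytest.fixture(scope="session")
def noisy_pattern(truth, geom):
    return simulate_pattern(truth, 0, 0, geom, noise=True)
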