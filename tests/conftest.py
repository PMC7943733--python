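import numpy as np
import pytest
from hypothesis import settings

from cswgs import PupilModel, SpotPattern

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pupil64():
    """Small uniform-illumination pupil for exact/oracle tests."""
    return PupilModel(aperture_px=64, illumination="uniform")


@pytest.fixture(scope="session")
def pupil64g():
    """Small pupil with the reference Gaussian truncation ratio."""
    return PupilModel().scaled(64)


@pytest.fixture(scope="session")
def pupil128():
    return PupilModel(aperture_px=128, illumination="uniform")


@pytest.fixture(scope="session")
def planar_cloud():
    """12 well-separated in-plane spots (separation >> diffraction limit)."""
    rng = np.random.default_rng(42)
    n = 12
    x = rng.uniform(-100, 100, n)
    y = rng.uniform(-100, 100, n)
    return SpotPattern(x, y, np.zeros(n))


@pytest.fixture(scope="session")
def weighted_cloud():
    """8 planar spots with non-uniform target intensities."""
    rng = np.random.default_rng(7)
    n = 8
    return SpotPattern(
        rng.uniform(-90, 90, n),
        rng.uniform(-90, 90, n),
        np.zeros(n),
        np.sqrt(rng.uniform(0.5, 1.0, n)),
    )
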