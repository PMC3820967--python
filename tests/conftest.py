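import numpy as np
import pytest

from framesip import RasterImage
from framesip.synthetic import SceneSpec, compose_family


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_srgb(rng):
    """A small random sRGB image."""
    return RasterImage(rng.random((48, 64, 3)), "sRGB")


@pytest.fixture(scope="session")
def default_family():
    """One deterministically generated P/PwF/PwF_S/MSc scene family."""
    return compose_family(SceneSpec(seed=5))
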