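import numpy as np
import pytest

from dbsmap.images import ImageVolume, TimeSeriesImage, centered_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    """A 21-cubed 1 mm grid centred on the world origin."""
    shape = (21, 21, 21)
    return centered_grid(shape, 1.0), shape


@pytest.fixture
def random_volume(rng):
    data = rng.normal(size=(7, 8, 9))
    aff = np.diag([2.0, 2.0, 2.5, 1.0])
    aff[:3, 3] = (-7.0, -8.0, -11.25)
    return ImageVolume(data, aff)


def make_mask_volume(data, affine=None):
    if affine is None:
        affine = np.eye(4)
    return ImageVolume(np.asarray(data, dtype=np.uint8), affine)
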