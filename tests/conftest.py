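import numpy as np
import pytest

from cnmtarget.preprocess import BoldSeries
from cnmtarget.volumes import BrainMask, VolumeGrid


@pytest.fixture
def small_grid():
    """A 10×12×10 grid of 3 mm voxels roughly centred on the midline."""
    affine = np.array([
        [3.0, 0, 0, -15.0],
        [0, 3.0, 0, -18.0],
        [0, 0, 3.0, -15.0],
        [0, 0, 0, 1.0],
    ])
    return VolumeGrid((10, 12, 10), affine)


@pytest.fixture
def rng():
    return np.random.default_rng(20230315)


@pytest.fixture
def random_series(small_grid, rng):
    """A small random float64 BOLD series (50 volumes, TR 1.7 s)."""
    data = rng.standard_normal((*small_grid.shape, 50))
    return BoldSeries(small_grid, data, tr=1.7)


@pytest.fixture
def full_mask(small_grid):
    return BrainMask(small_grid, np.ones(small_grid.shape, bool), name="all")
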