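import numpy as np
import pytest

from radtiles.features.preprocess import DiscretizedROI, ROIMask, VoxelVolume


@pytest.fixture
def worked_roi():
    """Single-slice 3x3 worked example: three 8-connected size-3 zones."""
    levels = np.array([[[1, 1, 2], [1, 2, 2], [3, 3, 3]]])
    return DiscretizedROI(levels=levels, mask=np.ones_like(levels, bool), n_levels=3)


@pytest.fixture
def random_volume():
    """A 24^3 noise volume with a 16^3 cubic ROI at 1 mm isotropic."""
    rng = np.random.default_rng(42)
    vol = VoxelVolume(rng.normal(0.0, 30.0, (24, 24, 24)), (1.0, 1.0, 1.0))
    m = np.zeros((24, 24, 24), bool)
    m[4:20, 4:20, 4:20] = True
    return vol, ROIMask(m)
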