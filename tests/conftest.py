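import numpy as np
import pytest

from petage.synthetic import GeneratorSpec
from petage.volumes import LabelAtlas, Mask, RegionInfo, Volume, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return VolumeGrid((8, 8, 8), (2.0, 2.0, 2.0))


@pytest.fixture
def toy_atlas():
    """10 voxels labelled 69, 5 labelled 70, 8 labelled 15 on an 8x8x8 grid."""
    grid = VolumeGrid((8, 8, 8), (2.0, 2.0, 2.0))
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels.ravel()[:10] = 69
    labels.ravel()[10:15] = 70
    labels.ravel()[20:28] = 15
    regions = [RegionInfo(69, "Paracentral_Lobule_L", True),
               RegionInfo(70, "Paracentral_Lobule_R", True),
               RegionInfo(15, "Frontal_Inf_Orb_L", False)]
    return LabelAtlas(grid, labels, regions)


@pytest.fixture
def tiny_spec():
    """Small, fast generator spec: 12 subjects on a 16x20x16 grid."""
    return GeneratorSpec(n_subjects=12, grid=VolumeGrid((16, 20, 16), (4.0, 4.0, 4.0)),
                         seed=7)


def random_volume(grid: VolumeGrid, rng: np.random.Generator) -> Volume:
    return Volume(grid, rng.normal(size=grid.shape))


def random_mask(grid: VolumeGrid, rng: np.random.Generator, p: float = 0.4) -> Mask:
    ind = rng.random(grid.shape) < p
    if not ind.any():
        ind.ravel()[0] = True
    return Mask(grid, ind)
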