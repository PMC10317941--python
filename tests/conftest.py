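import numpy as np
import pytest

from sirtdose import ScalarMap, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid4():
    """Tiny 4x4x4 grid of 2-mm voxels (voxel volume 0.008 ml)."""
    return VoxelGrid((4, 4, 4), (2.0, 2.0, 2.0))


@pytest.fixture
def unit_grid():
    """10-mm voxels: voxel volume exactly 1 ml."""
    return VoxelGrid((5, 5, 5), (10.0, 10.0, 10.0))


def make_map(grid: VoxelGrid, values, kind: str = "counts") -> ScalarMap:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = np.full(grid.shape, float(arr))
    return ScalarMap(grid, arr, kind)
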