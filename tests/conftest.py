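import numpy as np
import pytest
from scipy import ndimage

from vascprint import BinaryMask, VoxelVolume


def random_blob_mask(rng, shape, smooth=2.0, fill=0.3, voxel_size_um=5.0):
    """Random smooth blobby mask with roughly the requested fill fraction."""
    img = ndimage.gaussian_filter(rng.normal(size=shape), smooth)
    return BinaryMask(img > np.quantile(img, 1.0 - fill), voxel_size_um)


def random_mixed_mask(rng, max_side=32, voxel_size_um=5.0):
    """Mixture of the shapes the pipeline meets: tubes, balls, noise blobs."""
    shape = tuple(int(s) for s in rng.integers(8, max_side + 1, size=3))
    kind = rng.integers(3)
    if kind == 0:
        return random_blob_mask(rng, shape, smooth=rng.uniform(1, 3),
                                fill=rng.uniform(0.1, 0.4),
                                voxel_size_um=voxel_size_um)
    data = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.indices(shape)
    if kind == 1:  # ball
        c = [rng.uniform(2, s - 2) for s in shape]
        r = rng.uniform(2, min(shape) / 2)
        data = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r
    else:  # tube along a random axis
        ax = int(rng.integers(3))
        others = [i for i in range(3) if i != ax]
        c = [rng.uniform(2, shape[i] - 2) for i in others]
        r = rng.uniform(1.5, min(shape[others[0]], shape[others[1]]) / 3)
        coords = np.indices(shape)
        data = ((coords[others[0]] - c[0]) ** 2
                + (coords[others[1]] - c[1]) ** 2) <= r * r
    if rng.random() < 0.5:  # sprinkle noise voxels
        data = data | (rng.random(shape) < 0.02)
    return BinaryMask(data, voxel_size_um)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def small_volume(rng):
    data = rng.integers(0, 256, size=(6, 7, 8), dtype=np.uint8)
    return VoxelVolume(data, voxel_size_um=5.0)
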