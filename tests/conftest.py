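import numpy as np
import pytest

from ioa import BinaryMask, ImageGrid


def random_mask(rng, grid, p=0.3, ensure_nonempty=True):
    """Random mask on a grid; guarantees at least one set voxel by default."""
    voxels = rng.random(grid.shape) < p
    if ensure_nonempty and not voxels.any():
        idx = tuple(rng.integers(0, s) for s in grid.shape)
        voxels[idx] = True
    return BinaryMask(grid, voxels)


def random_grid(rng, max_extent=10):
    shape = tuple(int(rng.integers(2, max_extent + 1)) for _ in range(3))
    spacing = tuple(float(rng.uniform(0.5, 3.0)) for _ in range(3))
    origin = tuple(float(rng.uniform(-50, 50)) for _ in range(3))
    return ImageGrid(shape, spacing, origin)


def mask_pair_from_counts(tp, fp, fn, spacing=(1.0, 1.0, 1.0)):
    """Two interval masks on a 1x1xN line realizing the given counts.

    A = [0, tp+fp), B = [fp, fp+tp+fn); one spare background voxel keeps
    tn > 0.
    """
    n = tp + fp + fn + 1
    grid = ImageGrid((1, 1, n), spacing)
    a = np.zeros(grid.shape, dtype=bool)
    b = np.zeros(grid.shape, dtype=bool)
    a[0, 0, : tp + fp] = True
    b[0, 0, fp : fp + tp + fn] = True
    return BinaryMask(grid, a), BinaryMask(grid, b)


def ball_mask(grid, center_mm, radius_mm):
    """Voxel-center ball: set iff center within radius of the given point."""
    coords = [
        grid.origin_mm[ax] + np.arange(grid.shape[ax]) * grid.spacing_mm[ax]
        for ax in range(3)
    ]
    dz, dy, dx = np.meshgrid(*(c - m for c, m in zip(coords, center_mm)), indexing="ij")
    return BinaryMask(grid, dz * dz + dy * dy + dx * dx <= radius_mm**2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
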