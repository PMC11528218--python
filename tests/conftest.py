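import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ionoquant import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_cell_spec():
    """One noiseless nucleus, one channel."""
    return syn.StackSpec(
        shape_zyx=(12, 64, 64),
        cells=[syn.CellSpec((6, 32, 32), (3, 6, 6), (2000.0,))],
    )


@pytest.fixture
def fused_pair_spec():
    """Two nuclei fused through a basal slab over the bottom slices."""
    return syn.merge_scene_spec(2)


def random_blob_mask(rng, shape=(16, 32, 32), threshold=1.1):
    """Smooth random mask for morphology/EDT contract tests."""
    from scipy import ndimage

    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=3)
    return smooth > threshold * smooth.std()


def disjoint_ellipsoid_mask(rng, shape=(16, 64, 64), max_cells=4):
    """Union of well-separated solid ellipsoids: merge-free by construction.

    Each ellipsoid's slices are single convex components that overlap from
    slice to slice, so z-tracking and 3D connected components must agree.
    """
    mask = np.zeros(shape, dtype=bool)
    n = rng.integers(1, max_cells + 1)
    centers = []
    placed = 0
    attempts = 0
    while placed < n and attempts < 200:
        attempts += 1
        rz = rng.uniform(2, 4)
        ry = rng.uniform(3, 7)
        rx = rng.uniform(3, 7)
        c = (rng.uniform(rz, shape[0] - rz - 1),
             rng.uniform(ry, shape[1] - ry - 1),
             rng.uniform(rx, shape[2] - rx - 1))
        if any((c[1] - o[1]) ** 2 + (c[2] - o[2]) ** 2 < (ry + o[3] + 3) ** 2
               for o in centers):
            continue
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        ell = (((zz - c[0]) / rz) ** 2 + ((yy - c[1]) / ry) ** 2
               + ((xx - c[2]) / rx) ** 2) <= 1.0
        mask |= ell
        centers.append((c[0], c[1], c[2], max(ry, rx)))
        placed += 1
    return mask
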