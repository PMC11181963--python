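import numpy as np
import pytest

from valimet.core import PixelMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask_pair(rng):
    """Factory for random same-shape binary mask pairs."""

    def make(shape=(16, 16), p=0.4, spacing=None):
        ref = PixelMask(rng.random(shape) < p, spacing)
        pred = PixelMask(rng.random(shape) < p, spacing)
        return ref, pred

    return make


def block_mask(shape, blocks, spacing=None) -> PixelMask:
    grid = np.zeros(shape, dtype=bool)
    for (r0, r1, c0, c1) in blocks:
        grid[r0:r1, c0:c1] = True
    return PixelMask(grid, spacing)
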