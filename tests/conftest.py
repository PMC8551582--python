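import numpy as np
import pytest

from octaquant.slab_io import EnfaceSlab, Layer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_slab():
    """Uniform mid-gray 15x9 mm slab at ~18 um/px (834 x 500 grid)."""
    return EnfaceSlab(np.full((500, 834), 128, dtype=np.uint8), Layer.SVP)


def make_slab(pixels, layer=Layer.SVP, fov_mm=(15.0, 9.0), **kw):
    return EnfaceSlab(np.asarray(pixels, dtype=np.uint8), layer, fov_mm, **kw)


@pytest.fixture
def small_slab(rng):
    """Random 64x64 slab over a 1.152 x 1.152 mm field (18 um/px)."""
    px = rng.integers(0, 256, (64, 64), dtype=np.uint8)
    return EnfaceSlab(px, Layer.CC, fov_mm=(1.152, 1.152))
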