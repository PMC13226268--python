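import numpy as np
import pytest

from shrubshift.imaging import ChannelLayout, MaskRole, RasterImage, RegionMask
from shrubshift.simulate import ScenePreset, generate_scene_pair


@pytest.fixture
def uniform_rgb():
    """40x40 flat mid-gray RGB raster."""
    return RasterImage(np.full((40, 40, 3), 0.5), ChannelLayout.RGB)


@pytest.fixture
def square_prior():
    """Filled 20x20 square prior inside a 40x40 frame."""
    m = np.zeros((40, 40))
    m[10:30, 10:30] = 1.0
    return RegionMask(m, role=MaskRole.BUSH)


@pytest.fixture
def sandy_pair():
    """Small default sandy scene pair (fixed seed)."""
    return generate_scene_pair(ScenePreset(seed=7))


def gray_from_values(values, mask_weights=None):
    """1-row GRAY raster + all-ones (or given) mask from a value list."""
    vals = np.asarray(values, dtype=float)[None, :]
    img = RasterImage(vals, ChannelLayout.GRAY)
    w = np.ones_like(vals) if mask_weights is None else np.asarray(mask_weights, float)[None, :]
    return img, RegionMask(w)
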