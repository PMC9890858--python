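"""Shared analytic fixtures: simple shapes with closed-form trait values."""

import numpy as np
import pytest
from scipy import ndimage

from rootarch.image_io import BinaryMask

PX_PER_CM = 100.0      # 0.01 cm per pixel


def blank(h: int = 400, w: int = 400) -> np.ndarray:
    return np.zeros((h, w), dtype=bool)


@pytest.fixture
def bar_mask() -> BinaryMask:
    """Vertical bar, 200 x 10 px = 2.00 x 0.10 cm."""
    g = blank()
    g[100:300, 195:205] = True
    return BinaryMask(g, PX_PER_CM)


@pytest.fixture
def disk_mask() -> BinaryMask:
    """Filled disk of radius 40 px = 0.40 cm (large enough that the
    half-pixel boundary digitization stays below 2% of the area)."""
    g = blank()
    yy, xx = np.ogrid[:400, :400]
    g[(yy - 200) ** 2 + (xx - 200) ** 2 <= 40**2] = True
    return BinaryMask(g, PX_PER_CM)


@pytest.fixture
def cross_mask() -> BinaryMask:
    """Two 6-px-wide bars crossing at the center."""
    g = blank()
    g[100:300, 197:203] = True
    g[197:203, 100:300] = True
    return BinaryMask(g, PX_PER_CM)


@pytest.fixture
def y_mask() -> BinaryMask:
    """Y shape: vertical stem splitting into two diagonal branches."""
    from skimage.draw import line

    g = blank()
    for r in range(60, 201):
        g[r, 200] = True
    for (r0, c0, r1, c1) in [(200, 200, 380, 80), (200, 200, 380, 320)]:
        rr, cc = line(r0, c0, r1, c1)
        g[rr, cc] = True
    g = ndimage.binary_dilation(g, structure=np.ones((3, 3), bool))
    return BinaryMask(g, PX_PER_CM)


@pytest.fixture
def fixture_masks(bar_mask, disk_mask, cross_mask, y_mask) -> dict:
    return {"bar": bar_mask, "disk": disk_mask, "cross": cross_mask, "y": y_mask}
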