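import numpy as np
import pytest

from psmorph.image import SRImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def gaussian_ridge_ring(shape, pixel_size, centers, radius, sigma=25.0):
    """Image with Gaussian-cross-section rings at the given centers (nm)."""
    yy, xx = np.indices(shape)
    img = np.zeros(shape, dtype=float)
    for cx, cy in centers:
        d = np.hypot((xx + 0.5) * pixel_size - cx, (yy + 0.5) * pixel_size - cy)
        img += np.exp(-((d - radius) ** 2) / (2.0 * sigma ** 2))
    return SRImage(img, pixel_size)


def disk_image(shape, pixel_size, center, radius, value=1.0):
    """Binary-valued disk (nm units) rasterized on a pixel grid."""
    yy, xx = np.indices(shape)
    d = np.hypot((xx + 0.5) * pixel_size - center[0],
                 (yy + 0.5) * pixel_size - center[1])
    return SRImage(np.where(d <= radius, value, 0.0), pixel_size)


def ellipse_mask(shape, pixel_size, center, semi_x, semi_y):
    yy, xx = np.indices(shape)
    u = ((xx + 0.5) * pixel_size - center[0]) / semi_x
    v = ((yy + 0.5) * pixel_size - center[1]) / semi_y
    return (u ** 2 + v ** 2) <= 1.0
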