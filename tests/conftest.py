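import numpy as np
import pytest

from caftrack.spot_detection import Spot


def make_blob_image(shape, blobs, background=0.0, noise_sd=0.0, rng=None):
    """Render Gaussian blobs: list of (x, y, sigma_px, amplitude)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    for x, y, sigma, amp in blobs:
        img += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        img += (rng or np.random.default_rng(0)).normal(0, noise_sd, size=shape)
    return img


def spot(frame, x, y, quality=1.0):
    return Spot(frame=frame, x_px=float(x), y_px=float(y), quality=float(quality))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
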