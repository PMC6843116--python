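import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_filament(angle_deg: float, length_px: int = 120, size: int = 200, intensity: float = 110.0):
    """A straight 1-px filament through the image centre.

    Returns (image, truth_length_px) where the truth is the 8-neighbour
    edge-rule length of the drawn path.
    """
    img = np.zeros((size, size))
    dr = math.sin(math.radians(angle_deg))
    dc = math.cos(math.radians(angle_deg))
    r0 = size / 2 - length_px / 2 * dr
    c0 = size / 2 - length_px / 2 * dc
    rr, cc = draw_line(
        int(round(r0)), int(round(c0)),
        int(round(r0 + length_px * dr)), int(round(c0 + length_px * dc)),
    )
    img[rr, cc] = intensity
    truth = 0.0
    for i in range(len(rr) - 1):
        truth += math.sqrt(2) if (rr[i] != rr[i + 1] and cc[i] != cc[i + 1]) else 1.0
    return img, truth


def disks_image(centers, radius=8, size=128, intensity=200.0):
    img = np.zeros((size, size))
    for c in centers:
        rr, cc = draw_disk(c, radius, shape=img.shape)
        img[rr, cc] = intensity
    return img


@pytest.fixture
def filament_factory():
    return make_filament


@pytest.fixture
def disks_factory():
    return disks_image
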