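import numpy as np
import pytest

from ctradial.segmentation import ChannelImage, NucleusMask


def make_disk_mask(radius: int, pad: int = 4, pixel_size: float = 1.0) -> NucleusMask:
    """Rasterized disk: pixel centres within `radius` of the grid centre."""
    size = 2 * (radius + pad) + 1
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return NucleusMask(mask, pixel_size=pixel_size)


def make_ellipse_mask(a: int, b: int, pad: int = 4, pixel_size: float = 1.0) -> NucleusMask:
    size_y, size_x = 2 * (b + pad) + 1, 2 * (a + pad) + 1
    cy, cx = size_y // 2, size_x // 2
    yy, xx = np.mgrid[:size_y, :size_x]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return NucleusMask(mask, pixel_size=pixel_size)


@pytest.fixture
def disk_mask():
    return make_disk_mask


@pytest.fixture
def ellipse_mask():
    return make_ellipse_mask


@pytest.fixture
def flat_image():
    """Constant-intensity image the same shape as a mask."""

    def _make(mask: NucleusMask, value: float = 10.0, role: str = "dapi") -> ChannelImage:
        return ChannelImage(
            np.full(mask.mask.shape, value), role=role, pixel_size=mask.pixel_size,
            z_step=mask.z_step,
        )

    return _make
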