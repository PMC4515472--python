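import numpy as np
import pytest

from gutquant.imaging import ChannelStack, ImagePlane


def render_disks(shape, centres, radii_px, amplitude=1.0):
    """Binary-disk image used by segmentation tests."""
    img = np.zeros(shape, dtype=float)
    rr, cc = np.indices(shape)
    for (r, c), rad in zip(centres, radii_px):
        img[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = amplitude
    return img


@pytest.fixture
def disk_image():
    return render_disks


@pytest.fixture
def plane_factory():
    def make(pixels, pixel_size_um=1.0, channel="DAPI"):
        return ImagePlane(np.asarray(pixels, dtype=float), pixel_size_um, channel)

    return make


@pytest.fixture
def stack_factory():
    def make(channels, pixel_size_um=1.0):
        return ChannelStack(
            {k: np.asarray(v, dtype=float) for k, v in channels.items()},
            pixel_size_um,
        )

    return make
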