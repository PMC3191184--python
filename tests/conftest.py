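import numpy as np
import pytest

from punctacoloc import ChannelImage, RegionOfInterest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_roi():
    """Axis-aligned 3x3 polygon covering pixel centres (1..3, 1..3)."""
    return RegionOfInterest("polygon", [[1, 1], [3, 1], [3, 3], [1, 3]])


def make_image(pixels, bit_depth=8):
    return ChannelImage(np.asarray(pixels), bit_depth=bit_depth)
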