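import numpy as np
import pytest

from nucquant.image_io import ChannelImage
from nucquant.segmentation import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_mask(rng, shape=(64, 64), p=0.12):
    """Sparse random binary mask with small blob structure."""
    m = rng.random(shape) < p
    return BinaryMask(m)


def channel(values, name="red"):
    return ChannelImage(np.asarray(values, dtype=np.uint8), name)
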