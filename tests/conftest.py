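import numpy as np
import pytest

from histotex import QuantizedImage, ROIMask, RasterImage


def quantized_from_levels(levels, ng=None, spacing=5.0):
    """Wrap an integer level array (1..Ng) as a QuantizedImage + full ROI."""
    levels = np.asarray(levels, dtype=np.int32)
    ng = int(levels.max()) if ng is None else ng
    q = QuantizedImage(levels=levels, ng=ng,
                       bin_edges=np.linspace(0, 1, ng + 1),
                       pixel_spacing=spacing)
    return q, ROIMask(np.ones(levels.shape, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_quantized(rng):
    """8x8 image with 4 gray levels and a full ROI."""
    return quantized_from_levels(rng.integers(1, 5, (8, 8)), ng=4)


@pytest.fixture
def checkerboard():
    lv = np.indices((4, 4)).sum(axis=0) % 2 + 1
    return quantized_from_levels(lv, ng=2)


@pytest.fixture
def constant_image():
    return quantized_from_levels(np.ones((4, 4), dtype=int), ng=1)
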