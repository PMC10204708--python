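import numpy as np
import pytest


@pytest.fixture
def horizontal_bar():
    """Bright horizontal bar of full width 10 px on a zero background."""

    def make(full_width=10, contrast=100.0, shape=(100, 200), center=50):
        img = np.zeros(shape)
        half = full_width / 2.0
        rows = np.arange(shape[0])
        img[(rows >= center - half) & (rows < center + half), :] = contrast
        return img

    return make


@pytest.fixture
def two_bar_image():
    """A 4-px and a 30-px bright bar: the two-scale fixture."""
    img = np.zeros((120, 200))
    img[20:24, :] = 100.0
    img[60:90, :] = 100.0
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
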