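import numpy as np
import pytest

from peritex.imaging import GrayImage, QuantizedROI, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_quantized(rng: np.random.Generator, shape=(8, 8), ng=8, mask_fraction=0.8):
    """A random QuantizedROI with an irregular mask (helper, not a fixture)."""
    while True:
        mask = rng.random(shape) < mask_fraction
        if mask.sum() >= 4:
            break
    levels = np.where(mask, rng.integers(1, ng + 1, shape), 0).astype(np.int32)
    return QuantizedROI(
        levels=levels,
        mask=mask,
        n_levels=ng,
        norm_stats=(0.0, 1.0, -3.0, 3.0),
    )


@pytest.fixture
def ramp_image():
    """16x16 image whose intensity increases by 1 per row."""
    px = np.tile(np.arange(16.0)[:, None], (1, 16))
    return GrayImage(px, identifier="ramp")


@pytest.fixture
def full_mask():
    return ROIMask(np.ones((16, 16), dtype=bool))
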