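import numpy as np
import pytest

from glioscan.image import ImageVolume
from glioscan.synthetic import ScannerProfile, TumorShape, generate_tumor_volume


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def clean_profile():
    return ScannerProfile(pixel_spacing_mm=(2.0, 2.0), slice_thickness_mm=4.0,
                          bias_amplitude=0.0, noise_sd=0.0)


@pytest.fixture
def biased_profile():
    return ScannerProfile(pixel_spacing_mm=(2.0, 2.0), slice_thickness_mm=4.0,
                          bias_amplitude=0.3, noise_sd=0.0)


@pytest.fixture
def phantom(clean_profile):
    """Noiseless, bias-free phantom pair with masks."""
    return generate_tumor_volume(clean_profile, TumorShape(), seed=7)


def random_discretized(rng, shape=(5, 5, 3), ng=4, full_mask=True):
    """Random small discretized image + mask for oracle comparisons."""
    levels = rng.integers(1, ng + 1, size=shape)
    if full_mask:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = rng.random(shape) < 0.8
        if mask.sum() < 2:
            mask[0, 0, 0] = mask[1, 1, 1] = True
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int64), mask
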