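import numpy as np
import pytest

from vhfilter.preprocess import to_grayscale
from vhfilter.synth import SynthParams, generate_wbc_image


@pytest.fixture(scope="session")
def smear_rgb():
    """One deterministic synthetic smear (clean RGB image)."""
    clean, _ = generate_wbc_image(SynthParams(seed=11))
    return clean


@pytest.fixture(scope="session")
def smear_gray(smear_rgb):
    return to_grayscale(smear_rgb)


@pytest.fixture(scope="session")
def small_gray(smear_gray):
    """A 64x64 crop, cheap enough for the slower metric paths."""
    return smear_gray[80:144, 120:184].copy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
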