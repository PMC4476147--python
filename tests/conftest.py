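import numpy as np
import pytest

from edgecooc import FilterParams, build_filterbank


@pytest.fixture(scope="session")
def small_bank():
    """64x64 default-parameter bank shared by fast unit tests."""
    return build_filterbank(FilterParams(image_shape=(64, 64)))


@pytest.fixture(scope="session")
def medium_bank():
    """128x128 bank for placement-sensitive recovery tests."""
    return build_filterbank(FilterParams(image_shape=(128, 128)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
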