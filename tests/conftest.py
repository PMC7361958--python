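import numpy as np
import pytest

from eegdx import FeatureConfig, Segment, design_elliptic_bandpass


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def bandpass_256():
    """Default 0.1-60 Hz elliptic band-pass at fs = 256 Hz."""
    return design_elliptic_bandpass(fs=256.0)


@pytest.fixture
def random_segment(rng):
    """A 4096-sample single-channel segment of white noise at 256 Hz."""
    return Segment(
        samples=rng.standard_normal((1, 4096)),
        fs=256.0,
        duration_s=16.0,
    )


@pytest.fixture
def feature_config():
    return FeatureConfig()
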