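import numpy as np
import pytest

from astroroa import MovieStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_movie(frames, frame_rate=1.0, spatial_resolution=1.0):
    return MovieStack(np.asarray(frames, dtype=float), frame_rate, spatial_resolution)


@pytest.fixture
def noise_movie(rng):
    """64x64, 60-frame pure-noise movie (baseline 100, SD 1)."""
    return make_movie(100.0 + rng.standard_normal((60, 64, 64)))
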