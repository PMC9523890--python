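import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_views(rng):
    """Three centered random views sharing 20 samples."""
    views = [rng.normal(size=(20, p)) for p in (6, 5, 7)]
    return [X - X.mean(axis=0) for X in views]
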