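import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20150805)


@pytest.fixture
def s1_layer_grid():
    """Reference layer z grid: -10..10 um, 0.2 um spacing."""
    return np.round(np.arange(-10.0, 10.0 + 1e-9, 0.2), 10)
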