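import numpy as np
import pytest

from lexinet.environments import Environment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spread_env():
    """Six well-separated LAB chips; every 4-subset is a valid context."""
    chips = np.array([
        [0.0, 0.0, 0.0],
        [100.0, 0.0, 0.0],
        [0.0, 100.0, 0.0],
        [0.0, 0.0, 100.0],
        [80.0, 80.0, 0.0],
        [0.0, 80.0, 80.0],
    ])
    return Environment(chips=chips, label="base")
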