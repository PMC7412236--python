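import numpy as np
import pytest

from msrp import EmbedConfig, TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_series(rng):
    return TimeSeries(rng.normal(size=50))


@pytest.fixture
def default_config():
    return EmbedConfig(m=2, tau=1)
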