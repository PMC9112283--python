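import numpy as np
import pytest

from nmspont.model import EventParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hc_params():
    return EventParams(rate_per_s=0.012, amplitude_dff=0.8, duration_s=14.22)


@pytest.fixture
def sc_params():
    return EventParams(rate_per_s=0.005, amplitude_dff=0.5, duration_s=9.06)
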