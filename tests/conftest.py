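import numpy as np
import pytest

from cxsteer import CircuitConfig, FamiliarityConfig, TrialConfig


@pytest.fixture
def ccfg():
    return CircuitConfig()


@pytest.fixture
def fcfg():
    return FamiliarityConfig()


@pytest.fixture
def tcfg():
    return TrialConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class ConstantNormalRng:
    """Stand-in RNG whose normal() always returns the same value.

    Lets tests pair the left and right tuning-curve jitters, which a real
    generator draws independently.
    """

    def __init__(self, value: float):
        self.value = float(value)

    def normal(self, loc=0.0, scale=1.0, size=None):
        if size is not None:
            return np.full(size, self.value)
        return self.value


@pytest.fixture
def paired_noise_rng():
    return ConstantNormalRng
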