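import numpy as np
import pytest

from caaprio import WeightVector, default_framework


@pytest.fixture
def config():
    return default_framework()


@pytest.fixture
def panel_weights(config):
    """The seven published consensus weights as a WeightVector."""
    return WeightVector(config.factor_ids, config.weights)


@pytest.fixture
def rng():
    return np.random.default_rng(20210)
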