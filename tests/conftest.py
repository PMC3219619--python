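import numpy as np
import pytest

from shoalbayes import DecisionModel, ExperimentConfig


@pytest.fixture
def symmetric_model():
    return DecisionModel("symmetric", {"s": 2.5})


@pytest.fixture
def pair_config():
    return ExperimentConfig(group_size=2, condition_id="pair")


@pytest.fixture
def octet_config():
    return ExperimentConfig(group_size=8, condition_id="octet")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
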