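import numpy as np
import pytest

from sexratiosim import SimulationConfig, make_fixture


@pytest.fixture
def tiny_config() -> SimulationConfig:
    return make_fixture("tiny")


@pytest.fixture
def small_config() -> SimulationConfig:
    return make_fixture("small")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
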