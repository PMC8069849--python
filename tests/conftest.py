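import numpy as np
import pytest

from ecoqbn import bat_network, roshambo_network, spruce_graph


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def bat():
    return bat_network()


@pytest.fixture
def roshambo():
    return roshambo_network()


@pytest.fixture
def spruce():
    return spruce_graph()
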