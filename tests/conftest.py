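import numpy as np
import pytest

from polychron.fixtures import make_test_network


@pytest.fixture(scope="session")
def test_net():
    """The 20-neuron down-scaled network bundle (16 E / 4 I, out-degree 5)."""
    return make_test_network(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
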