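import numpy as np
import pytest

from spikesim.core import Network, NeuronParams


@pytest.fixture
def single_neuron():
    """One default LIF neuron with a raised resting potential so the
    free-run protocol (reset below rest) is well posed."""
    params = NeuronParams(C_m=0.2, g_l=0.02, E_l=-60.0, E_exc=0.0, E_inh=-80.0,
                          V_th=-50.0, V_reset=-70.0, tau_refrac=1.0)
    net = Network("one")
    net.add_population("p", 1, params)
    return net, params


@pytest.fixture
def driven_neuron():
    """A neuron with one excitatory and one inhibitory external driver."""
    net = Network("driven")
    net.add_population("p", 1, NeuronParams())
    net.add_sources("exc", 1)
    net.add_sources("inh", 1)
    d_e = net.add_source_drivers("exc", +1, 0.01, 5.0)[0]
    d_i = net.add_source_drivers("inh", -1, 0.01, 5.0)[0]
    net.set_weight(d_e, 0, 1.0)
    net.set_weight(d_i, 0, 1.0)
    return net, d_e, d_i


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
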