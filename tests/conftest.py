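import numpy as np
import pytest

from stdpnet import (
    GeometryConfig,
    Network,
    NeuronParams,
    SynapseParams,
    build_lattice,
    make_fixture,
)


@pytest.fixture
def neuron():
    return NeuronParams()


@pytest.fixture
def synapse():
    return SynapseParams()


@pytest.fixture
def two_neuron():
    """Two layers of one neuron with reciprocal synapses at weight 0.5."""
    net, _ = make_fixture("two_neuron")
    return net


@pytest.fixture
def three_layer_mini():
    net, _ = make_fixture("three_layer_mini")
    return net


def pair_network(w_forward: float = 0.5, w_backward: float = 0.5) -> Network:
    """A fresh two-neuron network with the given directed weights (0 -> 1, 1 -> 0)."""
    geometry = GeometryConfig(n_layers=2, per_layer=1)
    positions, layer_of = build_lattice(geometry)
    return Network(
        geometry=geometry,
        positions=positions,
        layer_of=layer_of,
        pre=np.array([0, 1]),
        post=np.array([1, 0]),
        weights=np.array([w_forward, w_backward], dtype=float),
    )
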