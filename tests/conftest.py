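import numpy as np
import pytest

from mediaplex import (
    DynamicsParams,
    LayerGraph,
    MultiplexNetwork,
    couple_layers,
    generate_layer,
    media_mask,
)


def make_multiplex(n, info_edges, epi_edges, rs_mode="none"):
    """Multiplex with identity coupling from explicit edge lists."""
    return MultiplexNetwork(
        LayerGraph.from_edges(n, info_edges),
        LayerGraph.from_edges(n, epi_edges),
        np.arange(n),
        rs_mode,
    )


@pytest.fixture(scope="session")
def small_multiplex():
    """Generated 100-node multiplex, random coupling, fixed seed."""
    info = generate_layer(100, 2.5, 10, seed=11)
    epi = generate_layer(100, 2.5, 5, seed=12)
    return couple_layers(info, epi, "none", seed=13)


@pytest.fixture(scope="session")
def medium_multiplex():
    """Generated 300-node multiplex, random coupling, fixed seed."""
    info = generate_layer(300, 2.5, 10, seed=21)
    epi = generate_layer(300, 2.5, 5, seed=22)
    return couple_layers(info, epi, "none", seed=23)


@pytest.fixture
def four_node_net():
    """Two distinct 4-node layers: info path 0-1-2-3, epi star at 0 + edge 2-3."""
    return make_multiplex(4, [(0, 1), (1, 2), (2, 3)], [(0, 1), (0, 2), (0, 3), (2, 3)])


@pytest.fixture
def default_mask():
    def _mask(net, eta=0.0, m=0.5):
        return media_mask(net, eta, m)

    return _mask


@pytest.fixture
def reference_params():
    """Prevalence-comparison parameter set: γ=0.4, λ=0.15, μ=0.5, δ=0.6."""
    return DynamicsParams(beta_u=0.4, gamma=0.4, mu=0.5, lambda_=0.15, delta=0.6, m=0.5)
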