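import networkx as nx
import numpy as np
import pytest

import epmoran as em


@pytest.fixture(scope="session")
def ba500():
    """One standard 500-node population graph shared across tests."""
    return em.generate_ba_graph(500, 4, seed=1)


@pytest.fixture(scope="session")
def ba_small():
    return em.generate_ba_graph(30, 2, seed=3)


@pytest.fixture
def triangle():
    return em.PopulationGraph(nx.complete_graph(3))


@pytest.fixture
def path4():
    return em.PopulationGraph(nx.path_graph(4))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
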