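import numpy as np
import pytest

from complexsampler import PPINetwork


@pytest.fixture
def toy_net():
    """A-B-C path plus pendant weights used across modules."""
    return PPINetwork([("A", "B", 0.5), ("B", "C", 1.0)])


@pytest.fixture
def square_net():
    """4-cycle A-B-C-D-A; the brute-force enumeration substrate."""
    return PPINetwork([("A", "B", 1.0), ("B", "C", 0.8),
                       ("C", "D", 0.6), ("D", "A", 0.9)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_network(rng, n_nodes=8, edge_prob=0.4):
    """Random weighted graph on n_nodes labelled N0..N{n-1}."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((nodes[i], nodes[j],
                              float(0.1 + 0.9 * rng.random())))
    return PPINetwork(edges, extra_nodes=nodes)
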