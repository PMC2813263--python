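import numpy as np
import pytest

from rolegraph.network import Assignment, Network


def make_random_network(n, p_edge, rng, weights=(1, 2, 3), ensure_edges=True):
    """Erdos-Renyi-style test network with integer weights."""
    while True:
        net = Network()
        for i in range(n):
            net.add_node(f"n{i}")
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p_edge:
                    net.add_edge(f"n{i}", f"n{j}", float(rng.choice(weights)))
        n_pairs = n * (n - 1) // 2
        if not ensure_edges or (0 < net.m < n_pairs):
            return net


def random_assignment(net, q, rng):
    return Assignment(rng.integers(0, q, size=net.n), q)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def net_factory():
    return make_random_network


@pytest.fixture
def toy():
    from rolegraph.benchmark import make_toy_fig1

    return make_toy_fig1(idealized=True)
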