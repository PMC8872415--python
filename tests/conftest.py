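from __future__ import annotations

import random
import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ldsrank import datasets


@pytest.fixture(scope="session")
def kite() -> nx.Graph:
    return datasets.kite_network()


@pytest.fixture(scope="session")
def growth_tree():
    """(network, center) with sphere counts [6, 11, 15, 19] from the center."""
    return datasets.ball_growth_tree()


@pytest.fixture(scope="session")
def synthetic():
    """Session-wide synthetic dataset at the default study conditions."""
    return datasets.make_synthetic_dataset(seed=0)


def random_connected_graph(rng: random.Random, n_max: int = 7) -> nx.Graph:
    """A random connected graph with 2..n_max string-labeled nodes."""
    n = rng.randint(2, n_max)
    while True:
        p = rng.uniform(0.25, 0.9)
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        if nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})


def random_graph(rng: random.Random, n_max: int = 8) -> nx.Graph:
    """A random (possibly disconnected) graph, isolated nodes allowed."""
    n = rng.randint(1, n_max)
    p = rng.uniform(0.0, 0.8)
    g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
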