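import numpy as np
import pytest

from phenomod import ProteinNetwork


@pytest.fixture
def path_graph():
    """a - b - c - d"""
    return ProteinNetwork([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def star_graph():
    """center c with leaves l1..l3"""
    return ProteinNetwork([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def triangle_graph():
    return ProteinNetwork([("a", "b"), ("b", "c"), ("a", "c")])


def random_network(rng: np.random.Generator, n: int = 20, p: float = 0.2) -> ProteinNetwork:
    """Small random graph with a spanning tree to guarantee connectivity."""
    names = [f"n{i:02d}" for i in range(n)]
    edges = [(names[i], names[int(rng.integers(i))]) for i in range(1, n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((names[i], names[j]))
    return ProteinNetwork(edges)
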