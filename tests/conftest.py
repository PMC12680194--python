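import numpy as np
import pytest

from nncrn import Graph, fixture_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def p4():
    """Path a-b-c-d on nodes 0..3."""
    return fixture_graph("path_4")


@pytest.fixture
def star4():
    """Star K_{1,3}: center 0, leaves 1..3."""
    return fixture_graph("star_4")


@pytest.fixture
def cycle5():
    return fixture_graph("cycle_5")


@pytest.fixture
def clique4():
    return fixture_graph("clique_4")


def random_simple_graph(n: int, m: int, seed: int) -> Graph:
    """Uniform simple graph with n nodes and m edges (test helper)."""
    r = np.random.default_rng(seed)
    chosen = set()
    while len(chosen) < m:
        u, v = int(r.integers(n)), int(r.integers(n))
        if u != v:
            chosen.add((min(u, v), max(u, v)))
    return Graph(n, sorted(chosen))
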