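"""Shared test fixtures: tiny hand-built graphs and the standard synthetic study."""

import numpy as np
import pytest

import netfate as nf


@pytest.fixture
def three_cycle() -> nf.SignedDigraph:
    """A -> B -| C -> A."""
    g = nf.SignedDigraph()
    g.add_edge("A", "B", 1)
    g.add_edge("B", "C", -1)
    g.add_edge("C", "A", 1)
    return g


@pytest.fixture
def two_two_cycles() -> nf.SignedDigraph:
    """Two vertex-disjoint 2-cycles A<->B, C<->D."""
    g = nf.SignedDigraph()
    for s, t in [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C")]:
        g.add_edge(s, t, 1)
    return g


@pytest.fixture
def dag() -> nf.SignedDigraph:
    g = nf.SignedDigraph()
    g.add_edge("A", "B", 1)
    g.add_edge("B", "C", 1)
    g.add_edge("A", "C", -1)
    return g


@pytest.fixture(scope="session")
def standard_fixture() -> nf.Fixture:
    """The default synthetic study (14 nodes, planted cycles of 3 and 2)."""
    return nf.make_fixture()


@pytest.fixture(scope="session")
def standard_study(standard_fixture) -> nf.StudyResult:
    """One full pipeline run on the standard fixture, shared across tests."""
    fx = standard_fixture
    return nf.run_study(fx.network, fx.expression, fx.markers, n_random=300, seed=0)


def random_digraph(seed: int, n_max: int = 12, p: float = 0.25) -> nf.SignedDigraph:
    """Erdos-Renyi-style signed digraph without self-loops."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    g = nf.SignedDigraph()
    for i in range(n):
        g.add_node(f"n{i}")
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}", 1 if rng.random() < 0.5 else -1)
    return g
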