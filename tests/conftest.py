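"""Shared fixtures: the small worked-example networks used across tests."""

import networkx as nx
import pytest

from plw import SimilarityModel


@pytest.fixture
def seed_example_graph() -> nx.Graph:
    """Vertex "1" with three mutually connected neighbours (a K4), plus a
    peripheral vertex "7" of equal degree but sparser neighbourhood."""
    G = nx.Graph()
    G.add_edges_from([("1", "2"), ("1", "3"), ("1", "4"),
                      ("2", "3"), ("2", "4"), ("3", "4")])
    # vertex 7: degree 3, no edges among its neighbours
    G.add_edges_from([("7", "4"), ("7", "8"), ("7", "9")])
    return G


@pytest.fixture
def similarity_example_graph() -> nx.Graph:
    """Adjacent vertices u, v of degree 4 sharing two common neighbours."""
    G = nx.Graph()
    G.add_edges_from([("u", "v"), ("u", "c1"), ("u", "c2"),
                      ("v", "c1"), ("v", "c2"), ("u", "x"), ("v", "y")])
    return G


@pytest.fixture
def elongator_pair_graph() -> nx.Graph:
    """Adjacent vertices of degrees 6 and 5 sharing four common neighbours."""
    G = nx.Graph()
    G.add_edge("u", "v")
    for c in ("c1", "c2", "c3", "c4"):
        G.add_edge("u", c)
        G.add_edge("v", c)
    G.add_edge("u", "x")  # brings deg(u) to 6
    return G


@pytest.fixture
def walk_example_model() -> SimilarityModel:
    """The labelled walk-example network: vertex 1 has three similarity-0.89
    edges; a 0.80-triangle 2-3-4; and a 0.45 bridge 4-7."""
    return SimilarityModel.from_similarities([
        ("1", "2", 0.89), ("1", "5", 0.89), ("1", "6", 0.89),
        ("2", "3", 0.80), ("3", "4", 0.80), ("2", "4", 0.80),
        ("4", "7", 0.45),
    ])
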