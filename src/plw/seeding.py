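"""Seed selection: rank vertices by degree × local-neighbourhood density.

A good seed sits centrally inside a dense region — likely a complex core.
Each vertex v is scored as

    score(v) = deg(v) · density(G_v)

where G_v is the local neighbourhood graph induced by {v} ∪ N_v and
density(G') = 2|E'| / (|V'|(|V'|−1)). The top λ fraction of vertices by
score form the seed set.

Edge cases fixed by convention: deg(v) = 0 → density 0 (score 0);
deg(v) = 1 → the induced 2-vertex, 1-edge graph has density 1 by the
formula, so score 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["neighbourhood_density", "seed_score", "select_seeds", "SeedRanking"]


def neighbourhood_density(net: nx.Graph, v: str) -> float:
    """Density of the subgraph induced by ``v`` and its neighbours, in [0, 1]."""
    if v not in net:
        raise ValueError(f"vertex {v!r} not in network")
    nbrs = set(net[v])
    if not nbrs:
        return 0.0
    n = len(nbrs) + 1
    # |E'| = deg(v) + edges among the neighbours.
    m = len(nbrs)
    for u in nbrs:
        for w in net[u]:
            if w in nbrs and u < w:
                m += 1
    return 2.0 * m / (n * (n - 1))


def seed_score(net: nx.Graph, v: str) -> float:
    """deg(v) times the density of v's local neighbourhood graph."""
    return net.degree(v) * neighbourhood_density(net, v)


@dataclass
class SeedRanking:
    """Full ranking of vertices by seed score plus the selected prefix.

    ``ranked`` is a permutation of all vertices in non-increasing score
    order; ``selected`` is its first ``x = round(lambda · |V|)`` elements.
    """

    scores: dict[str, float]
    ranked: list[str]
    lam: float
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected:
            x = int(math.floor(self.lam * len(self.ranked) + 0.5))  # round half up
            self.selected = self.ranked[:x]

    @property
    def seed_set(self) -> frozenset[str]:
        return frozenset(self.selected)

    def __len__(self) -> int:
        return len(self.selected)


def select_seeds(net: nx.Graph, lam: float = 0.3) -> SeedRanking:
    """Score all vertices and select the top-λ fraction as seeds.

    Ties are broken deterministically: higher degree first, then
    lexicographic protein ID. λ = 0 selects nothing; λ = 1 selects every
    vertex.
    """
    if not 0 <= lam <= 1:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    scores = {v: seed_score(net, v) for v in net}
    ranked = sorted(net, key=lambda v: (-scores[v], -net.degree(v), v))
    return SeedRanking(scores=scores, ranked=ranked, lam=lam)
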