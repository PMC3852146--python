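"""Planted-complex synthetic PPI networks with ground-truth catalogues.

Protein complexes manifest in PPI networks as dense regions, and
experimental interactomes are noisy: real intra-complex interactions are
missed (false negatives) and spurious background interactions appear.
The generator emulates exactly that premise: dense planted subgraphs
(the complexes) superimposed on a sparse Erdős–Rényi background, with
configurable intra-complex edge dropout and optional overlap between
complexes.

Complex sizes default to 3 + Poisson(3.68), clipped to [3, 20], giving a
mean near 6.68 proteins — the average complex size in the CYC2008
curated yeast catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_io import ComplexSet

__all__ = ["SyntheticSpec", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of a planted-complex network.

    n_background : total vertex count (proteins are named ``P0000``…).
    p_background : Erdős–Rényi background edge probability.
    n_complexes : number of planted complexes.
    size_min, size_max, size_poisson_mean : complex sizes are drawn as
        ``size_min + Poisson(size_poisson_mean)`` clipped to
        [size_min, size_max]; defaults give a CYC2008-like mean ≈ 6.68.
    density : probability of each intra-complex edge before dropout.
    edge_dropout : probability an intra-complex edge is then removed,
        emulating false-negative interactions.
    overlap_fraction : share of complexes that reuse ≥ 1 protein from an
        earlier complex (overlapping complexes exist in real catalogues).
    rng_seed : generator seed; output is deterministic given the spec.
    """

    n_background: int = 1000
    p_background: float = 0.005
    n_complexes: int = 30
    size_min: int = 3
    size_max: int = 20
    size_poisson_mean: float = 3.68
    density: float = 0.9
    edge_dropout: float = 0.1
    overlap_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_background", "density", "edge_dropout", "overlap_fraction"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.size_min < 3:
            raise ValueError("planted complexes need at least 3 members")
        if self.size_max > self.n_background:
            raise ValueError("complex size cannot exceed total vertex count")


def generate(spec: SyntheticSpec) -> tuple[nx.Graph, ComplexSet]:
    """Build the network and its exact ground-truth catalogue.

    Returns a simple undirected graph over all ``n_background`` vertices
    (isolated background vertices included) and the planted complexes in
    planting order. Planted edges and background edges can coincide; the
    union is taken.
    """
    rng = np.random.default_rng(spec.rng_seed)
    names = [f"P{i:04d}" for i in range(spec.n_background)]
    G: nx.Graph = nx.Graph()
    G.add_nodes_from(names)

    # Background: G(n, p) via the fast edge-skipping generator, relabelled.
    bg = nx.fast_gnp_random_graph(
        spec.n_background, spec.p_background, seed=int(rng.integers(2**31))
    )
    G.add_edges_from((names[u], names[v]) for u, v in bg.edges())

    complexes: list[frozenset[str]] = []
    used: set[str] = set()
    for k in range(spec.n_complexes):
        size = min(
            spec.size_max, spec.size_min + int(rng.poisson(spec.size_poisson_mean))
        )
        overlap = bool(used) and rng.random() < spec.overlap_fraction
        members: list[str] = []
        if overlap:
            members.append(str(rng.choice(sorted(used))))
        fresh_pool = [n for n in names if n not in used]
        need = size - len(members)
        if need > len(fresh_pool):
            raise ValueError(
                f"complex {k}: needs {need} fresh proteins, only {len(fresh_pool)} left"
            )
        members.extend(rng.choice(fresh_pool, size=need, replace=False))
        used.update(members)
        members.sort()
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < spec.density and rng.random() >= spec.edge_dropout:
                    G.add_edge(members[i], members[j])
        complexes.append(frozenset(members))

    truth = ComplexSet(complexes, [{"planted": k} for k in range(len(complexes))])
    return G, truth
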