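"""Common neighbour similarity and the derived walk model.

Two interacting proteins that share many interaction partners are likely
to share biological function. *Common neighbour similarity* quantifies
this as the cosine similarity of the proteins' closed-neighbourhood
indicator vectors: for vertices u, v with closed neighbourhoods
V_u = {u} ∪ N_u and V_v = {v} ∪ N_v,

    sim(u, v) = |V_u ∩ V_v| / sqrt(|V_u| · |V_v|)

For adjacent u, v with c common (open) neighbours this is
(c + 2) / sqrt((deg(u)+1)(deg(v)+1)) — the "+2" counts the two proteins
themselves, which each belong to both closed neighbourhoods.

The :class:`SimilarityModel` derives from these similarities the two
quantities a probabilistic local walk needs at each step:

* a transition distribution per vertex — the walker moves from v to
  neighbour u with probability sim(v, u) / Σ_p sim(v, p);
* a penalty per edge, γ = max(1 − sim, γ_floor), deducted from the walk's
  energy budget; the floor (default 0.01) guarantees termination even on
  similarity-1 edges.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = ["common_neighbour_similarity", "SimilarityModel", "GAMMA_FLOOR"]

#: Minimum per-step energy penalty; keeps every walk finite.
GAMMA_FLOOR = 0.01


def common_neighbour_similarity(net: nx.Graph, u: str, v: str) -> float:
    """Cosine similarity of the closed neighbourhoods of ``u`` and ``v``.

    Returns a value in [0, 1]. Defined for any distinct pair of vertices,
    though the walk model only ever evaluates it on edges.

    Raises
    ------
    ValueError
        If ``u == v`` or either vertex is not in the graph.
    """
    if u == v:
        raise ValueError("similarity is defined for distinct vertices only")
    if u not in net or v not in net:
        missing = u if u not in net else v
        raise ValueError(f"vertex {missing!r} not in network")
    Vu = set(net[u]) | {u}
    Vv = set(net[v]) | {v}
    return len(Vu & Vv) / math.sqrt(len(Vu) * len(Vv))


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class SimilarityModel:
    """Per-edge similarities, walk penalties and per-vertex transitions.

    Build with :meth:`from_network` (similarities computed from graph
    topology) or :meth:`from_similarities` (explicit edge labels, e.g. a
    worked example with prescribed weights).

    Attributes
    ----------
    edge_similarity : dict
        Canonical (lexicographically ordered) vertex pair → similarity.
    edge_penalty : dict
        Canonical pair → γ = max(1 − similarity, gamma_floor).
    """

    def __init__(
        self,
        edge_similarity: Mapping[tuple[str, str], float],
        gamma_floor: float = GAMMA_FLOOR,
    ):
        if not 0 < gamma_floor <= 1:
            raise ValueError("gamma_floor must be in (0, 1]")
        self.gamma_floor = float(gamma_floor)
        self.edge_similarity: dict[tuple[str, str], float] = {}
        adjacency: dict[str, list[tuple[str, float]]] = {}
        for (u, v), s in edge_similarity.items():
            if not 0 <= s <= 1:
                raise ValueError(f"similarity of ({u}, {v}) outside [0, 1]: {s}")
            key = _edge_key(u, v)
            self.edge_similarity[key] = float(s)
            adjacency.setdefault(u, []).append((v, float(s)))
            adjacency.setdefault(v, []).append((u, float(s)))
        self.edge_penalty = {
            k: max(1.0 - s, self.gamma_floor) for k, s in self.edge_similarity.items()
        }
        # Transition tables: neighbour array + cumulative probabilities,
        # enabling O(log deg) inverse-CDF sampling.
        self._neighbours: dict[str, np.ndarray] = {}
        self._cumprobs: dict[str, np.ndarray] = {}
        self._probs: dict[str, np.ndarray] = {}
        for v, nbrs in adjacency.items():
            nbrs.sort()  # deterministic neighbour order
            names = np.array([n for n, _ in nbrs], dtype=object)
            sims = np.array([s for _, s in nbrs], dtype=float)
            total = sims.sum()
            if total > 0:
                probs = sims / total
            else:
                # Defensive: adjacent vertices always have sim > 0 under the
                # closed-neighbourhood formula, but explicit labels may not.
                probs = np.full(len(sims), 1.0 / len(sims))
            self._neighbours[v] = names
            self._probs[v] = probs
            self._cumprobs[v] = np.cumsum(probs)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_network(
        cls, net: nx.Graph, gamma_floor: float = GAMMA_FLOOR
    ) -> "SimilarityModel":
        """Compute common neighbour similarity for every edge of ``net``.

        Only edges are scored — the walk never jumps between non-adjacent
        vertices — so the cost is O(Σ_v deg(v)²) worst case and near
        O(|E|·avg-deg) in practice. Degree-0 vertices get an empty
        transition list.
        """
        sims: dict[tuple[str, str], float] = {}
        closed = {v: set(net[v]) | {v} for v in net}
        for u, v in net.edges():
            s = len(closed[u] & closed[v]) / math.sqrt(len(closed[u]) * len(closed[v]))
            sims[_edge_key(u, v)] = s
        model = cls(sims, gamma_floor=gamma_floor)
        for v in net:  # register isolated vertices
            if v not in model._neighbours:
                model._neighbours[v] = np.array([], dtype=object)
                model._probs[v] = np.array([], dtype=float)
                model._cumprobs[v] = np.array([], dtype=float)
        return model

    @classmethod
    def from_similarities(
        cls,
        edges: Iterable[tuple[str, str, float]] | Mapping[tuple[str, str], float],
        gamma_floor: float = GAMMA_FLOOR,
    ) -> "SimilarityModel":
        """Build from explicit ``(u, v, similarity)`` labels."""
        if isinstance(edges, Mapping):
            return cls(edges, gamma_floor=gamma_floor)
        return cls({(u, v): s for u, v, s in edges}, gamma_floor=gamma_floor)

    # -- queries -----------------------------------------------------------

    @property
    def vertices(self) -> list[str]:
        return list(self._neighbours)

    def similarity(self, u: str, v: str) -> float:
        return self.edge_similarity[_edge_key(u, v)]

    def penalty(self, u: str, v: str) -> float:
        return self.edge_penalty[_edge_key(u, v)]

    def degree(self, v: str) -> int:
        return len(self._neighbours[v])

    def transitions(self, v: str) -> tuple[Sequence[str], np.ndarray]:
        """Neighbour list of ``v`` and the matching transition probabilities."""
        return self._neighbours[v], self._probs[v]

    def sample_neighbour(self, v: str, rng: np.random.Generator) -> str:
        """Draw the walker's next vertex from ``v``'s transition distribution."""
        cum = self._cumprobs[v]
        if len(cum) == 0:
            raise ValueError(f"vertex {v!r} has no neighbours to walk to")
        i = int(np.searchsorted(cum, rng.random(), side="right"))
        return self._neighbours[v][min(i, len(cum) - 1)]

    def to_records(self) -> list[tuple[str, str, float]]:
        """Edge similarities as sorted (u, v, sim) records, for TSV dumps."""
        return [(u, v, s) for (u, v), s in sorted(self.edge_similarity.items())]
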