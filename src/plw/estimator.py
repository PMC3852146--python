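"""The PLW clustering estimator: the full pipeline in one fit call.

Protein complex detection by Probabilistic Local Walks (PLW) proceeds in
four stages over a PPI graph:

1. seed selection — rank vertices by degree × neighbourhood density,
   keep the top λ fraction;
2. similarity model — common neighbour similarity per edge, transition
   distributions per vertex, energy penalties per edge;
3. probabilistic local walks — w energy-bounded walks per seed,
   accumulating visit counts;
4. core mining and attachment — z-scores of ln(visitCount) pick each
   seed's core (size ≥ 3, deduplicated); proteins interacting with more
   than half a core are attached to form the predicted cluster.

The estimator follows scikit-learn conventions (``fit``/``fit_predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
it composes with sklearn model-selection tooling; ``X`` is a
:class:`networkx.Graph` rather than a feature matrix.
"""

from __future__ import annotations

import warnings

import networkx as nx
from sklearn.base import BaseEstimator

from .attachments import add_attachments
from .core_mining import mine_cores
from .network_io import ComplexSet
from .seeding import select_seeds
from .similarity import SimilarityModel
from .walks import VisitCounts, WalkConfig, run_walks

__all__ = ["PLW"]


class PLW(BaseEstimator):
    """Probabilistic Local Walks protein-complex detector.

    Parameters
    ----------
    lam : float, default 0.3
        Seed fraction λ; the top ``round(lam·|V|)`` vertices by seed score
        are expanded. 0.3 is the recommended operating point.
    alpha : float, default 2.0
        Starting energy per walk; bounds each walk to the seed's
        α-vicinity on the similarity-weighted graph.
    w : int, default 100
        Walks per seed.
    significance : float, default 0.005
        Upper-tail significance level for core membership (z of
        ln(visitCount) against the pooled distribution).
    gamma_floor : float, default 0.01
        Minimum per-step energy penalty; guarantees walk termination.
    min_core_size : int, default 3
        Cores smaller than this are discarded.
    random_state : int, default 0
        Seed for the walk RNG; fixed value ⇒ bit-identical output.

    Attributes
    ----------
    similarity_model_ : SimilarityModel
    seed_ranking_ : SeedRanking
    visit_counts_ : VisitCounts
    cores_ : ComplexSet            — pre-attachment cores
    clusters_ : ComplexSet         — final predicted complexes
    mean_walk_length_ : float      — diagnostic q, average steps per walk

    Examples
    --------
    >>> import networkx as nx
    >>> from plw import PLW
    >>> est = PLW(lam=1.0, random_state=7)
    >>> clusters = est.fit_predict(nx.complete_graph(5))
    >>> sorted(map(len, clusters))
    [5]
    """

    def __init__(
        self,
        lam: float = 0.3,
        alpha: float = 2.0,
        w: int = 100,
        significance: float = 0.005,
        gamma_floor: float = 0.01,
        min_core_size: int = 3,
        random_state: int = 0,
    ):
        self.lam = lam
        self.alpha = alpha
        self.w = w
        self.significance = significance
        self.gamma_floor = gamma_floor
        self.min_core_size = min_core_size
        self.random_state = random_state

    def fit(self, X: nx.Graph, y=None) -> "PLW":
        """Run the full pipeline on a PPI graph.

        ``X`` must be an undirected simple graph; vertex labels are the
        protein IDs (coerced to ``str``). ``y`` is ignored (unsupervised).
        """
        if not isinstance(X, nx.Graph) or X.is_directed():
            raise TypeError("X must be an undirected networkx.Graph")
        if any(not isinstance(v, str) for v in X):
            X = nx.relabel_nodes(X, {v: str(v) for v in X})
        if nx.number_of_selfloops(X):
            raise ValueError("network must be simple (self-loops present)")
        self.n_vertices_ = X.number_of_nodes()
        self.n_edges_ = X.number_of_edges()
        if self.n_vertices_ == 0:
            warnings.warn("empty network; no clusters", stacklevel=2)
            self._empty_fit()
            return self

        self.seed_ranking_ = select_seeds(X, self.lam)
        if len(self.seed_ranking_) == 0:
            self._empty_fit()
            return self
        self.similarity_model_ = SimilarityModel.from_network(
            X, gamma_floor=self.gamma_floor
        )
        cfg = WalkConfig(
            alpha=self.alpha,
            w=self.w,
            gamma_floor=self.gamma_floor,
            rng_seed=self.random_state,
        )
        seeds = [s for s in self.seed_ranking_.selected if X.degree(s) > 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degree-0 seeds already filtered
            self.visit_counts_ = run_walks(self.similarity_model_, seeds, cfg)
        self.mean_walk_length_ = self.visit_counts_.mean_steps
        self.cores_ = mine_cores(
            self.visit_counts_,
            p=self.significance,
            seed_order=seeds,
            min_size=self.min_core_size,
        )
        self.clusters_ = add_attachments(X, self.cores_)
        return self

    def _empty_fit(self) -> None:
        self.seed_ranking_ = None
        self.similarity_model_ = None
        self.visit_counts_ = VisitCounts()
        self.mean_walk_length_ = 0.0
        self.cores_ = ComplexSet()
        self.clusters_ = ComplexSet()

    def fit_predict(self, X: nx.Graph, y=None) -> ComplexSet:
        """Fit and return the predicted clusters."""
        return self.fit(X, y).clusters_

    def stage_counts(self) -> dict[str, float]:
        """Per-stage diagnostics of the last fit, machine-readable."""
        if not hasattr(self, "clusters_"):
            raise RuntimeError("estimator is not fitted")
        return {
            "vertices": self.n_vertices_,
            "edges": self.n_edges_,
            "seeds": len(self.seed_ranking_) if self.seed_ranking_ else 0,
            "cores": len(self.cores_),
            "clusters": len(self.clusters_),
            "mean_walk_length": round(self.mean_walk_length_, 4),
        }
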