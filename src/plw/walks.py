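"""Energy-bounded probabilistic local walks and visit-count accumulation.

For each seed s, ``w`` walks are simulated. A walk starts at s with energy
budget α. Each iteration: if the current vertex is not the seed, its visit
count is incremented; a neighbour is drawn with probability proportional to
common neighbour similarity; the edge penalty γ = max(1 − sim, γ_floor) is
deducted; the walker moves. The walk stops once energy drops below zero —
the energy-negative step is taken but the vertex it reaches is never
counted. The budget keeps every counted vertex within the seed's
α-vicinity on the similarity-weighted graph, so cores stay local.

Defaults follow the recommended operating point: α = 2.00 (covers
neighbours-of-neighbours, tolerating missing interactions), w = 100 walks
per seed, γ floor 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .similarity import GAMMA_FLOOR, SimilarityModel

__all__ = ["WalkConfig", "VisitCounts", "run_walks", "replay_walk", "ENERGY_EPS"]

#: Guard against float drift at exact-zero energy boundaries: a walk stops
#: only when energy is below -ENERGY_EPS, so a budget that lands exactly on
#: 0.00 (e.g. ten 0.20 penalties from 2.00) still allows the next step.
ENERGY_EPS = 1e-9


@dataclass
class WalkConfig:
    """Parameters of the probabilistic local walk stage.

    alpha : starting energy budget per walk (> 0).
    w : number of walks per seed (≥ 1).
    gamma_floor : minimum per-step penalty, in (0, 1].
    rng_seed : seed for the walk RNG; fixed seed ⇒ bit-identical counts.
    """

    alpha: float = 2.0
    w: int = 100
    gamma_floor: float = GAMMA_FLOOR
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.w < 1:
            raise ValueError("w must be at least 1")
        if not 0 < self.gamma_floor <= 1:
            raise ValueError("gamma_floor must be in (0, 1]")

    @property
    def max_steps(self) -> int:
        """Hard cap on walk length: ceil(alpha / gamma_floor) + 1 steps."""
        return int(np.ceil(self.alpha / self.gamma_floor)) + 1


@dataclass
class VisitCounts:
    """Sparse cumulative visit counts per (seed, vertex), over all walks.

    ``counts[s][v]`` is the number of arrivals at v over the w walks seeded
    at s; the seed itself is never counted. ``mean_steps`` is the average
    number of steps per walk (the diagnostic q).
    """

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    n_walks: int = 0
    total_steps: int = 0

    @property
    def mean_steps(self) -> float:
        return self.total_steps / self.n_walks if self.n_walks else 0.0

    def seed_total(self, s: str) -> int:
        return sum(self.counts.get(s, {}).values())

    def items(self):
        """Iterate (seed, vertex, count) in deterministic insertion order."""
        for s, per in self.counts.items():
            for v, c in per.items():
                yield s, v, c

    def __len__(self) -> int:
        return sum(len(per) for per in self.counts.values())


def run_walks(
    model: SimilarityModel,
    seeds: list[str] | frozenset[str],
    cfg: WalkConfig | None = None,
) -> VisitCounts:
    """Simulate ``cfg.w`` probabilistic local walks from each seed.

    Seeds are processed in the given order (sets are sorted first) with a
    single RNG stream, so identical inputs and ``cfg.rng_seed`` reproduce
    the counts exactly. Degree-0 seeds are skipped with a warning. Walks
    may traverse other seeds; those arrivals are counted like any other
    non-seed-of-this-walk vertex.
    """
    cfg = cfg or WalkConfig()
    if isinstance(seeds, (set, frozenset)):
        seeds = sorted(seeds)
    rng = np.random.default_rng(cfg.rng_seed)
    vc = VisitCounts()
    for s in seeds:
        if s not in model._neighbours:
            raise ValueError(f"seed {s!r} not in similarity model")
        if model.degree(s) == 0:
            warnings.warn(f"seed {s!r} has no neighbours; skipped", stacklevel=2)
            continue
        per: dict[str, int] = vc.counts.setdefault(s, {})
        for _ in range(cfg.w):
            v = s
            energy = cfg.alpha
            steps = 0
            while True:
                if v != s:
                    per[v] = per.get(v, 0) + 1
                u = model.sample_neighbour(v, rng)
                energy -= max(1.0 - model.similarity(v, u), cfg.gamma_floor)
                v = u
                steps += 1
                if energy < -ENERGY_EPS:
                    break
            vc.n_walks += 1
            vc.total_steps += steps
        if not per:
            del vc.counts[s]
    return vc


def replay_walk(
    model: SimilarityModel,
    path: list[str],
    alpha: float = 2.0,
    gamma_floor: float = GAMMA_FLOOR,
) -> list[float]:
    """Deterministically replay a vertex sequence, returning the energy trace.

    Applies the same penalty rule as :func:`run_walks`: after traversing
    edge (v, u) the remaining energy drops by max(1 − sim(v, u),
    gamma_floor). The trace starts at ``alpha`` and has one entry per step;
    an empty or single-vertex path yields ``[alpha]``.

    Raises
    ------
    ValueError
        If consecutive vertices in ``path`` are not adjacent in the model.
    """
    trace = [float(alpha)]
    energy = float(alpha)
    for i, (v, u) in enumerate(zip(path, path[1:])):
        try:
            sim = model.similarity(v, u)
        except KeyError:
            raise ValueError(
                f"step {i + 1}: vertices {v!r} and {u!r} are not adjacent"
            ) from None
        energy -= max(1.0 - sim, gamma_floor)
        trace.append(energy)
    return trace
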