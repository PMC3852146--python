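"""Mining protein-complex cores from visit counts via log z-scores.

Vertices visited unusually often from a seed are the seed's core
companions. All nonzero visit counts (pooled across every seed) are
log-transformed — the log lessens the impact of heavy-tailed outliers —
and standardised with one global mean and population standard deviation.
A (seed, vertex) pair is significant when its z-score exceeds the
upper-tail standard-normal critical value at significance level p
(default p = 0.005, critical value ≈ 2.576). Each seed's candidate core
is the seed plus its significant vertices; cores with two or fewer
proteins and exact duplicates are discarded.
"""

from __future__ import annotations

import math
import warnings

from scipy import stats

from .network_io import ComplexSet
from .walks import VisitCounts

__all__ = ["SignificanceModel", "mine_cores"]


class SignificanceModel:
    """Global ln(visitCount) statistics and the significance cut.

    Statistics pool every nonzero count across all seeds; the standard
    deviation is the population sd (divide by N) for bit-reproducibility.
    """

    def __init__(self, vc: VisitCounts, p: float = 0.005):
        if not 0 < p < 1:
            raise ValueError(f"significance level must be in (0, 1), got {p}")
        self.p = p
        self.z_threshold = float(stats.norm.ppf(1.0 - p))
        logs = [math.log(c) for _, _, c in vc.items()]
        self.n = len(logs)
        if self.n == 0:
            self.mean = self.sd = 0.0
            return
        self.mean = sum(logs) / self.n
        self.sd = math.sqrt(sum((x - self.mean) ** 2 for x in logs) / self.n)

    def is_significant(self, count: int) -> bool:
        """Upper-tail test of ln(count) against the pooled statistics.

        Zero variance (all counts equal) makes nothing significant.
        """
        if self.sd == 0:
            return False
        return (math.log(count) - self.mean) / self.sd > self.z_threshold


def mine_cores(
    vc: VisitCounts,
    p: float = 0.005,
    seed_order: list[str] | None = None,
    min_size: int = 3,
) -> ComplexSet:
    """Convert visit counts into deduplicated complex cores.

    For each seed s, the candidate core is {s} ∪ {v : z(ln count(s, v))
    exceeds the upper-tail critical value for p}. Cores smaller than
    ``min_size`` are dropped, as are exact duplicates (first occurrence in
    ``seed_order`` wins; default order is the counts' insertion order,
    i.e. the order seeds were walked).
    """
    model = SignificanceModel(vc, p=p)
    if model.n and model.sd == 0:
        warnings.warn(
            "all visit counts are equal (zero log-variance); no cores mined",
            stacklevel=2,
        )
    cores: list[frozenset[str]] = []
    labels: list[dict] = []
    seen: set[frozenset[str]] = set()
    order = seed_order if seed_order is not None else list(vc.counts)
    for s in order:
        per = vc.counts.get(s)
        if per is None:
            continue
        candidate = frozenset(
            {s} | {v for v, c in per.items() if model.is_significant(c)}
        )
        if len(candidate) < min_size or candidate in seen:
            continue
        seen.add(candidate)
        cores.append(candidate)
        labels.append({"seed": s, "stage": "core"})
    return ComplexSet(cores, labels)
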