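"""Match-based evaluation of predicted complexes against a benchmark.

Matching uses the neighbourhood affinity score

    NA(p, b) = |p ∩ b|² / (|p| · |b|)

A prediction p matches a benchmark complex b when NA(p, b) ≥ ω (default
ω = 0.2, inclusive). From the match relation:

* Ncp — predictions matching ≥ 1 benchmark complex; precision = Ncp/|P|
* Ncb — benchmark complexes matched by ≥ 1 prediction; recall = Ncb/|B|
* F-measure — harmonic mean of precision and recall.

Complementing the match counts, with T_ij = |b_i ∩ p_j| the
benchmark-by-prediction overlap matrix:

* Sn  = Σ_i max_j T_ij / Σ_i |b_i|   (complex-wise sensitivity)
* PPV = Σ_j max_i T_ij / Σ_j Σ_i T_ij (cluster-wise positive predictive value)
* Accuracy = sqrt(Sn · PPV)          (geometric accuracy)

Benchmark proteins absent from the analysed network are kept in the
benchmark sets; this is conservative for recall and Sn.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .network_io import ComplexSet

__all__ = ["neighbourhood_affinity", "evaluate", "EvalReport"]


def neighbourhood_affinity(p: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """NA(p, b) = |p∩b|²/(|p||b|), in [0, 1]; 1 iff the sets are equal."""
    if not p or not b:
        raise ValueError("neighbourhood affinity requires non-empty sets")
    inter = len(set(p) & set(b))
    return inter * inter / (len(p) * len(b))


@dataclass
class EvalReport:
    """Evaluation metrics for one prediction set against one benchmark."""

    omega: float
    n_predicted: int
    n_benchmark: int
    ncp: int
    ncb: int
    precision: float
    recall: float
    f_measure: float
    sn: float
    ppv: float
    accuracy: float
    #: mean cluster size and number of distinct proteins covered by P
    avg_predicted_size: float = 0.0
    n_covered_proteins: int = 0

    def summary(self) -> str:
        return (
            f"complexes={self.n_predicted} avg_size={self.avg_predicted_size:.2f} "
            f"covered={self.n_covered_proteins} Ncp={self.ncp} Ncb={self.ncb} "
            f"precision={self.precision:.3f} recall={self.recall:.3f} "
            f"f_measure={self.f_measure:.3f} sn={self.sn:.3f} ppv={self.ppv:.3f} "
            f"accuracy={self.accuracy:.3f}"
        )


def evaluate(pred: ComplexSet, bench: ComplexSet, omega: float = 0.2) -> EvalReport:
    """Score predictions against a benchmark catalogue.

    An empty prediction set yields all-zero metrics with a warning rather
    than an error (a run can legitimately find nothing).
    """
    if not 0 < omega <= 1:
        raise ValueError(f"omega must be in (0, 1], got {omega}")
    P = list(pred)
    B = list(bench)
    if not P or not B:
        warnings.warn("empty prediction or benchmark set; metrics are zero", stacklevel=2)
        return EvalReport(omega, len(P), len(B), 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    matched_p = [False] * len(P)
    matched_b = [False] * len(B)
    # T_ij overlap matrix, kept sparse-by-row
    row_max = [0] * len(B)  # max_j T_ij
    col_max = [0] * len(P)  # max_i T_ij
    total_T = 0
    for j, p in enumerate(P):
        for i, b in enumerate(B):
            t = len(p & b)
            total_T += t
            row_max[i] = max(row_max[i], t)
            col_max[j] = max(col_max[j], t)
            if t and t * t / (len(p) * len(b)) >= omega:
                matched_p[j] = True
                matched_b[i] = True

    ncp = sum(matched_p)
    ncb = sum(matched_b)
    precision = ncp / len(P)
    recall = ncb / len(B)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    sn = sum(row_max) / sum(len(b) for b in B)
    ppv = sum(col_max) / total_T if total_T > 0 else 0.0
    covered = pred.proteins()
    return EvalReport(
        omega=omega,
        n_predicted=len(P),
        n_benchmark=len(B),
        ncp=ncp,
        ncb=ncb,
        precision=precision,
        recall=recall,
        f_measure=f,
        sn=sn,
        ppv=ppv,
        accuracy=math.sqrt(sn * ppv),
        avg_predicted_size=sum(len(p) for p in P) / len(P),
        n_covered_proteins=len(covered),
    )
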