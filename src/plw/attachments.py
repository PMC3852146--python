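"""Expanding cores into full complexes under the core-attachment model.

A predicted complex is a tight core plus loosely bound attachments: every
protein outside the core that interacts with strictly more than half of
the core's members is attached. All candidates are judged against the
original core simultaneously — an attachment never helps another
candidate qualify — so the result is independent of evaluation order.
"""

from __future__ import annotations

import networkx as nx

from .network_io import ComplexSet

__all__ = ["attachments_for_core", "add_attachments"]

#: Fraction of core members a protein must interact with (strict >).
ATTACHMENT_THRESHOLD = 0.5


def attachments_for_core(net: nx.Graph, core: frozenset[str]) -> frozenset[str]:
    """Proteins v ∉ core with |N_v ∩ core| / |core| > 0.5.

    Candidates are restricted to neighbours of core members; any other
    vertex has zero core adjacency and trivially fails the threshold.
    """
    size = len(core)
    if size == 0:
        return frozenset()
    tally: dict[str, int] = {}
    for u in core:
        if u not in net:
            continue
        for v in net[u]:
            if v not in core:
                tally[v] = tally.get(v, 0) + 1
    return frozenset(v for v, k in tally.items() if k / size > ATTACHMENT_THRESHOLD)


def add_attachments(net: nx.Graph, cores: ComplexSet) -> ComplexSet:
    """Expand each core into a cluster; deduplicate clusters as sets.

    Core order is preserved; two cores yielding the same cluster keep the
    first occurrence. A core with no qualifying attachment passes through
    unchanged.
    """
    clusters: list[frozenset[str]] = []
    labels: list[dict] = []
    seen: set[frozenset[str]] = set()
    for i, core in enumerate(cores):
        cluster = core | attachments_for_core(net, core)
        if cluster in seen:
            continue
        seen.add(cluster)
        clusters.append(cluster)
        label = dict(cores.labels[i]) if cores.labels else {}
        label["stage"] = "cluster"
        label["core_size"] = len(core)
        labels.append(label)
    return ComplexSet(clusters, labels)
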