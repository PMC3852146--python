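"""Reading, cleaning and writing PPI networks and protein-complex catalogues.

A protein–protein interaction (PPI) network is an undirected simple graph
whose vertices are opaque protein identifier strings. Networks are held in
:class:`networkx.Graph`; complex catalogues in :class:`ComplexSet`.

Flat-file formats follow the conventions of DIP/BioGRID exports and
MCL-style cluster files: networks are tab/whitespace-separated edge lists
(first two tokens per line are the interacting proteins, extra columns are
ignored, ``#`` starts a comment); complex files hold one complex per line
as whitespace-separated protein IDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "ComplexSet",
    "load_network",
    "load_complexes",
    "write_network",
    "write_complexes",
]


class ParseError(ValueError):
    """Raised when an input line cannot be interpreted."""


@dataclass
class ComplexSet:
    """An ordered collection of protein complexes (sets of protein IDs).

    Parameters
    ----------
    complexes : list of frozenset of str
        The member sets, in a meaningful order (input line order for a
        benchmark catalogue, mining order for predictions).
    labels : list of dict, optional
        Per-complex provenance, e.g. ``{"seed": "YDR190C", "stage": "core"}``.
    """

    complexes: list[frozenset[str]] = field(default_factory=list)
    labels: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if self.labels and len(self.labels) != len(self.complexes):
            raise ValueError("labels must match complexes in length")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return self.complexes == other.complexes

    def as_canonical(self) -> list[frozenset[str]]:
        """Order-independent canonical form: sorted by size desc, then members."""
        return sorted(self.complexes, key=lambda c: (-len(c), sorted(c)))

    def filter_by_size(self, min_size: int = 3) -> "ComplexSet":
        """Drop complexes with fewer than ``min_size`` members.

        Both benchmark catalogues and predicted cluster lists are routinely
        restricted to complexes of at least three proteins before
        evaluation; pairs are dominated by interaction-data quality rather
        than clustering quality.
        """
        keep = [i for i, c in enumerate(self.complexes) if len(c) >= min_size]
        return ComplexSet(
            [self.complexes[i] for i in keep],
            [self.labels[i] for i in keep] if self.labels else [],
        )

    def proteins(self) -> frozenset[str]:
        """Union of all member proteins."""
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return frozenset(out)


def load_network(path: str | Path) -> nx.Graph:
    """Load a PPI network from a whitespace/tab-separated edge list.

    Self-loops and duplicate edges (undirected: ``(u, v)`` equals
    ``(v, u)``) are removed. Vertices are induced from edges only; protein
    IDs are case-sensitive opaque strings. Cleaning counts are stored on
    the returned graph under ``G.graph``:

    ``n_lines`` (non-comment, non-blank lines read), ``n_self_loops``
    (discarded), ``n_duplicates`` (collapsed).

    Raises
    ------
    ParseError
        If a non-comment line carries fewer than two tokens.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    G: nx.Graph = nx.Graph()
    n_lines = n_self = n_dup = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least two protein IDs, got {line!r}"
                )
            n_lines += 1
            u, v = tokens[0], tokens[1]
            if u == v:
                n_self += 1
                continue
            if G.has_edge(u, v):
                n_dup += 1
                continue
            G.add_edge(u, v)
    G.graph.update(n_lines=n_lines, n_self_loops=n_self, n_duplicates=n_dup)
    return G


def write_network(G: nx.Graph, path: str | Path) -> None:
    """Write an edge list with canonical (lexicographic) pair ordering."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in G.edges()):
            fh.write(f"{u}\t{v}\n")


def load_complexes(path: str | Path) -> ComplexSet:
    """Load an MCL-style complex catalogue (one complex per line).

    Line order is preserved; duplicate IDs within a line collapse (set
    semantics). A file with no non-blank lines yields an empty set with a
    warning rather than an error.
    """
    path = Path(path)
    complexes: list[frozenset[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            complexes.append(frozenset(line.split()))
    if not complexes:
        warnings.warn(f"{path}: no complexes found", stacklevel=2)
    return ComplexSet(complexes)


def write_complexes(cs: ComplexSet | Iterable[Sequence[str]], path: str | Path) -> None:
    """Write complexes one per line, deterministically ordered.

    Complexes are ordered by size descending, ties broken lexicographically
    by sorted member list; members are sorted within a line. Re-loading the
    file therefore yields the canonical form of the input.
    """
    if not isinstance(cs, ComplexSet):
        cs = ComplexSet([frozenset(c) for c in cs])
    with open(path, "w", encoding="utf-8") as fh:
        for c in cs.as_canonical():
            fh.write(" ".join(sorted(c)) + "\n")
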