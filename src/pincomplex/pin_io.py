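"""Protein interaction network and complex-catalog I/O.

A protein interaction network (PIN) is represented as a simple undirected
:class:`networkx.Graph` whose nodes are opaque protein-ID strings.  Weighted
networks carry a non-negative ``weight`` attribute per edge.  Complex
catalogs are ordered lists of protein sets, one complex per line on disk.

Protein IDs are case-sensitive and never normalized here; mapping between
accession systems (e.g. DIP identifiers vs. gene names) is the caller's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger("pincomplex")

__all__ = [
    "ComplexCatalog",
    "EdgeListError",
    "read_edge_list",
    "write_edge_list",
    "read_complexes",
    "write_complexes",
    "induced_subgraph",
    "neighbors_of_set",
]


class EdgeListError(ValueError):
    """Raised for malformed edge-list input."""


@dataclass
class ComplexCatalog:
    """Ordered list of protein complexes (node sets), optionally named/scored.

    Order is stable: downstream ranking and evaluation depend on it.
    Each complex is a frozenset of at least 2 distinct protein IDs when read
    from disk; programmatically-built catalogs may hold anything.
    """

    complexes: list[frozenset[str]] = field(default_factory=list)
    names: list[str | None] = field(default_factory=list)
    scores: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if not self.names:
            self.names = [None] * len(self.complexes)
        if not self.scores:
            self.scores = [None] * len(self.complexes)
        if len(self.names) != len(self.complexes) or len(self.scores) != len(self.complexes):
            raise ValueError("names/scores length must match complexes")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.complexes]

    def restricted_to(self, nodes: Iterable[str], min_size: int = 2) -> "ComplexCatalog":
        """Drop members absent from *nodes*; discard complexes falling below *min_size*."""
        nodes = set(nodes)
        kept: list[frozenset[str]] = []
        kept_names: list[str | None] = []
        n_dropped = 0
        for cx, name in zip(self.complexes, self.names):
            reduced = cx & nodes
            if len(reduced) >= min_size:
                kept.append(frozenset(reduced))
                kept_names.append(name)
            else:
                n_dropped += 1
        if n_dropped:
            logger.warning("dropped %d complexes reduced below size %d by the network", n_dropped, min_size)
        return ComplexCatalog(kept, kept_names)


def read_edge_list(path: str | PathLike, weighted: bool = False) -> nx.Graph:
    """Read a tab-separated edge list into a simple undirected graph.

    Lines are ``proteinA<TAB>proteinB[<TAB>weight]``; ``#``-prefixed lines are
    comments.  Duplicate edges are collapsed and self-loops dropped (both with
    a logged count), matching the simple-graph model of the PIN.
    """
    g = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            want = 3 if weighted else 2
            if len(parts) < want:
                raise EdgeListError(f"{path}:{lineno}: expected {want} tab-separated fields, got {len(parts)}")
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise EdgeListError(f"{path}:{lineno}: empty protein ID")
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dup += 1
            if weighted:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise EdgeListError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                if w < 0:
                    raise EdgeListError(f"{path}:{lineno}: negative weight {w}")
                g.add_edge(u, v, weight=w)
            else:
                g.add_edge(u, v)
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge line(s)", path, n_dup)
    return g


def write_edge_list(graph: nx.Graph, path: str | PathLike) -> None:
    """Write a graph as a sorted TSV edge list (round-trips with :func:`read_edge_list`)."""
    weighted = any("weight" in d for _, _, d in graph.edges(data=True))
    lines = []
    for u, v, d in graph.edges(data=True):
        a, b = sorted((u, v))
        if weighted:
            lines.append(f"{a}\t{b}\t{d.get('weight', 0.0):.10g}")
        else:
            lines.append(f"{a}\t{b}")
    with open(path, "w") as fh:
        for line in sorted(lines):
            fh.write(line + "\n")


def read_complexes(path: str | PathLike) -> ComplexCatalog:
    """Read a catalog: one complex per line, whitespace-separated protein IDs.

    A leading token ending in ``:`` names the complex.  Complexes with fewer
    than 2 distinct members after deduplication are dropped with a warning.
    An empty file yields an empty catalog.
    """
    complexes: list[frozenset[str]] = []
    names: list[str | None] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()  # '#' starts a comment (e.g. #score=)
            if not line:
                continue
            tokens = line.split()
            name = None
            if tokens and tokens[0].endswith(":"):
                name = tokens[0][:-1]
                tokens = tokens[1:]
            members = frozenset(tokens)
            if len(members) < 2:
                n_dropped += 1
                logger.warning("%s:%d: complex with <2 distinct members dropped", path, lineno)
                continue
            complexes.append(members)
            names.append(name)
    if n_dropped:
        logger.warning("%s: dropped %d undersized complex(es)", path, n_dropped)
    return ComplexCatalog(complexes, names)


def write_complexes(catalog: ComplexCatalog, path: str | PathLike) -> None:
    """Write a catalog, one complex per line; scores go into a trailing comment."""
    with open(path, "w") as fh:
        for cx, name, score in zip(catalog.complexes, catalog.names, catalog.scores):
            prefix = f"{name}: " if name else ""
            suffix = f"\t#score={score:.6g}" if score is not None else ""
            fh.write(prefix + " ".join(sorted(cx)) + suffix + "\n")


def induced_subgraph(graph: nx.Graph, members: Iterable[str]) -> nx.Graph:
    """Subgraph of *graph* induced by *members*; unknown members dropped with a warning.

    Edge weights are carried over.  The result is a standalone copy.
    """
    members = set(members)
    unknown = members - set(graph.nodes)
    if unknown:
        logger.warning("induced_subgraph: %d member(s) absent from graph dropped", len(unknown))
        members -= unknown
    return nx.Graph(graph.subgraph(members))


def neighbors_of_set(graph: nx.Graph, members: Iterable[str]) -> set[str]:
    """All nodes outside *members* adjacent to at least one member."""
    members = set(members)
    out: set[str] = set()
    for m in members:
        if m in graph:
            out.update(graph.neighbors(m))
    return out - members
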