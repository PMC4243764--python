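"""Maximal-clique enumeration over the (filtered) PIN.

Maximal cliques seed the complex detection pipeline.  Enumeration is
worst-case exponential but fast on PPI networks, which are sparse; the
Bron–Kerbosch recursion with pivoting behind :func:`networkx.find_cliques`
is used.  Output order is deterministic — size descending, then
lexicographic member list — because downstream tie-breaking depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = ["CliqueSet", "maximal_cliques"]


@dataclass
class CliqueSet:
    """Maximal cliques of size >= min_size, in canonical order."""

    cliques: list[frozenset[str]]
    min_size: int

    def __len__(self) -> int:
        return len(self.cliques)

    def __iter__(self):
        return iter(self.cliques)


def clique_sort_key(members: frozenset[str]) -> tuple[int, tuple[str, ...]]:
    return (-len(members), tuple(sorted(members)))


def maximal_cliques(graph: nx.Graph, min_size: int = 3) -> CliqueSet:
    """All maximal cliques of *graph* with at least *min_size* members.

    A maximal clique smaller than *min_size* is dropped, not extended.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    cliques = [frozenset(c) for c in nx.find_cliques(graph) if len(c) >= min_size]
    cliques.sort(key=clique_sort_key)
    return CliqueSet(cliques=cliques, min_size=min_size)
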