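"""The 10-dimensional feature vector describing a candidate complex.

Features are computed on the subgraphs a node set induces in the paired
unweighted / weighted PIN.  Four come from the unweighted graph — density,
mean and median degree, mean clustering coefficient — and six from the
weighted graph — weighted density, mean and maximum weighted degree, mean
edge weight, and the topological changes T5 and T7.

The weighted density sums edge weights over ordered node pairs and divides by
|V|(|V|-1), so each edge contributes twice and a uniform-weight clique has
density equal to that weight; with all weights 1 it coincides with the
unweighted density.

Topological change T_i measures the fraction of edges lost when the weight
cutoff rises from i to i+1: with E_i = {e : w(e) > i},
T_i = (|E_i| - |E_{i+1}|) / |E_i| (0 when E_i is empty).  Only T5 and T7
enter the canonical vector; the full T1..T7 profile is available from
:func:`topological_changes`.

The canonical feature order is fixed by :data:`FEATURE_NAMES`; fitted models
depend on it.
"""

from __future__ import annotations

import statistics
from typing import Iterable

import networkx as nx
import numpy as np

from .pin_io import induced_subgraph

__all__ = [
    "FEATURE_NAMES",
    "DegenerateComplexError",
    "unweighted_density",
    "degree_stats_unweighted",
    "clustering_coefficient_mean",
    "weighted_density",
    "degree_stats_weighted",
    "mean_edge_weight",
    "topological_changes",
    "feature_vector",
]

#: Canonical order of the 10 features; model weight vectors follow it.
FEATURE_NAMES: tuple[str, ...] = (
    "density_u",
    "mean_degree_u",
    "median_degree_u",
    "clustering_u",
    "density_w",
    "mean_degree_w",
    "max_degree_w",
    "mean_weight_w",
    "t5",
    "t7",
)

#: Weight cutoffs probed by the topological-change features.
_T_CUTOFFS = range(1, 9)


class DegenerateComplexError(ValueError):
    """Raised when featurizing a node set with fewer than 2 members."""


def unweighted_density(sub: nx.Graph) -> float:
    """|E| over the maximum possible |V|(|V|-1)/2; requires at least 2 nodes."""
    n = sub.number_of_nodes()
    if n < 2:
        raise DegenerateComplexError("density needs >= 2 nodes")
    return sub.number_of_edges() / (n * (n - 1) / 2)


def degree_stats_unweighted(sub: nx.Graph) -> tuple[float, float]:
    """(mean, median) of within-subgraph degrees."""
    degrees = [d for _, d in sub.degree()]
    if not degrees:
        raise DegenerateComplexError("degree statistics need >= 1 node")
    return float(np.mean(degrees)), float(statistics.median(degrees))


def clustering_coefficient_mean(sub: nx.Graph) -> float:
    """Mean over nodes of 2|E_nbrs| / k(k-1), taken as 0 for nodes with k <= 1."""
    n = sub.number_of_nodes()
    if n == 0:
        raise DegenerateComplexError("clustering coefficient needs >= 1 node")
    cc = nx.clustering(sub)  # identical to the 2|E_i|/k(k-1) formula with 0 at k<=1
    return float(sum(cc.values()) / n)


def _weights(sub: nx.Graph) -> list[float]:
    return [d.get("weight", 0.0) for _, _, d in sub.edges(data=True)]


def weighted_density(sub: nx.Graph) -> float:
    """Sum of w(u,v) over ordered pairs, divided by |V|(|V|-1).

    Each edge contributes twice, so a complete graph of uniform weight w has
    density exactly w.
    """
    n = sub.number_of_nodes()
    if n < 2:
        raise DegenerateComplexError("weighted density needs >= 2 nodes")
    return 2.0 * sum(_weights(sub)) / (n * (n - 1))


def degree_stats_weighted(sub: nx.Graph) -> tuple[float, float]:
    """(mean, max) of within-subgraph weighted degrees (sums of incident weights)."""
    if sub.number_of_nodes() == 0:
        raise DegenerateComplexError("degree statistics need >= 1 node")
    degrees = [d for _, d in sub.degree(weight="weight")]
    return float(np.mean(degrees)), float(max(degrees))


def mean_edge_weight(sub: nx.Graph) -> float:
    """Mean internal edge weight; 0 for an edgeless set."""
    w = _weights(sub)
    return float(np.mean(w)) if w else 0.0


def topological_changes(sub: nx.Graph) -> np.ndarray:
    """T1..T7 edge-loss fractions across integer weight cutoffs 1..8."""
    w = np.asarray(_weights(sub), dtype=float)
    counts = [int((w > i).sum()) for i in _T_CUTOFFS]
    out = np.zeros(7)
    for i in range(7):
        if counts[i] > 0:
            out[i] = (counts[i] - counts[i + 1]) / counts[i]
    return out


def feature_vector(members: Iterable[str], gu: nx.Graph, gw: nx.Graph) -> np.ndarray:
    """The canonical 10-feature descriptor of *members* over the paired PINs."""
    members = set(members)
    if len(members) < 2:
        raise DegenerateComplexError(f"cannot featurize a set of {len(members)} member(s)")
    su = induced_subgraph(gu, members)
    sw = induced_subgraph(gw, members)
    mean_u, med_u = degree_stats_unweighted(su)
    mean_w, max_w = degree_stats_weighted(sw)
    t = topological_changes(sw)
    vec = np.array(
        [
            unweighted_density(su),
            mean_u,
            med_u,
            clustering_coefficient_mean(su),
            weighted_density(sw),
            mean_w,
            max_w,
            mean_edge_weight(sw),
            t[4],
            t[6],
        ]
    )
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature encountered")
    return vec
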