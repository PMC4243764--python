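"""The clique-seeded complex detection pipeline: filter, grow, merge.

Detection runs in four stages over the paired unweighted/weighted PIN with a
fitted scoring model:

1. enumerate maximal cliques (the seeds);
2. rank the cliques by model score and drop any lower-ranked clique sharing
   at least ``clique_overlap_nodes`` members with a retained one (dense PINs
   produce heavily overlapping cliques);
3. grow each survivor greedily: among the seed's neighbors, repeatedly add
   the one whose inclusion raises the score most, until no neighbor improves
   it — the neighborhood is computed once from the seed;
4. rank the grown candidates and, for each pair exceeding the Jaccard
   overlap threshold ``merg_thred``, merge them when the union scores higher
   than the better candidate, otherwise remove the worse one.

Ranking ties break by larger size first, then lexicographically smaller
member list, making the whole pipeline deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

from .clique_enum import CliqueSet, maximal_cliques
from .complex_features import feature_vector
from .pin_io import ComplexCatalog, neighbors_of_set
from .scoring_model import RegressionModel, score

logger = logging.getLogger("pincomplex")

__all__ = [
    "Candidate",
    "PipelineParams",
    "filter_cliques",
    "grow_candidate",
    "overlap",
    "merge_filter",
    "detect",
]


@dataclass
class Candidate:
    """A candidate complex: member set, current model score, seed-clique id."""

    members: frozenset[str]
    score: float
    provenance: int = -1
    score_trace: list[float] = field(default_factory=list)


@dataclass
class PipelineParams:
    """Detection parameters.

    ``clique_min_size``/``clique_overlap_nodes`` are paired per the method's
    calibration: overlap threshold 2 for cliques of size >= 3, 3 for size
    >= 4.  ``merg_thred`` defaults to 0.8, the best-performing setting.
    ``clique_overlap_strict`` switches the clique-overlap test from >= to >;
    ``dynamic_neighborhood`` recomputes the growth frontier after each
    accepted node.
    """

    model: RegressionModel
    clique_min_size: int = 3
    clique_overlap_nodes: int | None = None
    merg_thred: float = 0.8
    clique_overlap_strict: bool = False
    dynamic_neighborhood: bool = False

    def __post_init__(self) -> None:
        if self.clique_overlap_nodes is None:
            self.clique_overlap_nodes = 2 if self.clique_min_size <= 3 else 3
        if not (0 < self.merg_thred <= 1):
            raise ValueError("merg_thred must lie in (0, 1]")


def _rank_key(c: Candidate) -> tuple[float, int, tuple[str, ...]]:
    return (-c.score, -len(c.members), tuple(sorted(c.members)))


def _scored(members: frozenset[str], model: RegressionModel, gu: nx.Graph, gw: nx.Graph, provenance: int = -1) -> Candidate:
    return Candidate(members, score(model, feature_vector(members, gu, gw)), provenance)


def filter_cliques(
    cliques: CliqueSet | Iterable[frozenset[str]],
    params: PipelineParams,
    gu: nx.Graph,
    gw: nx.Graph,
) -> list[Candidate]:
    """Score-rank the cliques and remove heavily overlapping lower-ranked ones.

    Scanning from the top of the ranking, a clique sharing at least
    ``clique_overlap_nodes`` members (strictly more under
    ``clique_overlap_strict``) with any retained higher-ranked clique is
    removed.  Survivors are returned in rank order.
    """
    scored = [
        _scored(frozenset(c), params.model, gu, gw, provenance=i)
        for i, c in enumerate(cliques)
    ]
    scored.sort(key=_rank_key)
    retained: list[Candidate] = []
    for cand in scored:
        ok = True
        for keeper in retained:
            common = len(cand.members & keeper.members)
            if (common > params.clique_overlap_nodes) or (
                not params.clique_overlap_strict and common == params.clique_overlap_nodes
            ):
                ok = False
                break
        if ok:
            retained.append(cand)
    logger.info("filter_cliques: retained %d/%d cliques", len(retained), len(scored))
    return retained


def grow_candidate(
    cand: Candidate,
    gu: nx.Graph,
    gw: nx.Graph,
    model: RegressionModel,
    dynamic_neighborhood: bool = False,
    record_trace: bool = False,
) -> Candidate:
    """Greedy score-guided growth of a seed candidate.

    The neighbor whose addition yields the highest score strictly above the
    current one is added (ties: lexicographically smallest node) and removed
    from the frontier; growth stops when no neighbor improves the score.  By
    default the frontier is computed once from the seed; with
    ``dynamic_neighborhood`` it is recomputed after each accepted node.
    """
    members = cand.members
    current = cand.score
    frontier = neighbors_of_set(gu, members)
    trace = [current] if record_trace else []
    while frontier:
        best_node: str | None = None
        best_score = current
        for v in sorted(frontier):
            s = score(model, feature_vector(members | {v}, gu, gw))
            if s > best_score:
                best_node, best_score = v, s
        if best_node is None:
            break
        members = members | {best_node}
        current = best_score
        if record_trace:
            trace.append(current)
        if dynamic_neighborhood:
            frontier = neighbors_of_set(gu, members)
        else:
            frontier.discard(best_node)
    return Candidate(members, current, cand.provenance, score_trace=trace)


def overlap(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard overlapping rate |a∩b| / |a∪b|."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("overlap of two empty sets is undefined")
    return len(a & b) / len(union)


def merge_filter(
    cands: Sequence[Candidate],
    params: PipelineParams,
    gu: nx.Graph,
    gw: nx.Graph,
) -> list[Candidate]:
    """Single-pass overlap-driven merging/removal of candidate complexes.

    Exact-duplicate member sets are collapsed first.  Candidates are ranked
    by score; for each candidate in rank order, every lower-ranked candidate
    exceeding the Jaccard threshold is merged into it when the union scores
    strictly higher, and removed otherwise.  Survivors are returned in scan
    order (post-merge scores may reorder them; callers re-rank for output).
    """
    seen: set[frozenset[str]] = set()
    unique: list[Candidate] = []
    for c in sorted(cands, key=_rank_key):
        if c.members not in seen:
            seen.add(c.members)
            unique.append(c)
    removed = [False] * len(unique)
    for i, ci in enumerate(unique):
        if removed[i]:
            continue
        for j in range(i + 1, len(unique)):
            if removed[j]:
                continue
            cj = unique[j]
            if overlap(ci.members, cj.members) > params.merg_thred:
                union = ci.members | cj.members
                s_union = score(params.model, feature_vector(union, gu, gw))
                if s_union > ci.score:
                    ci = Candidate(union, s_union, ci.provenance)
                    unique[i] = ci
                removed[j] = True
    out = [c for c, r in zip(unique, removed) if not r]
    logger.info("merge_filter: %d candidates -> %d", len(unique), len(out))
    return out


def detect(
    gu: nx.Graph,
    gw: nx.Graph,
    model: RegressionModel,
    params: PipelineParams | None = None,
) -> ComplexCatalog:
    """End-to-end detection: cliques -> filter -> grow -> merge.

    Returns the predicted complexes, scored, in deterministic rank order.
    """
    if params is None:
        params = PipelineParams(model=model)
    cliques = maximal_cliques(gu, min_size=params.clique_min_size)
    logger.info("detect: %d maximal cliques of size >= %d", len(cliques), params.clique_min_size)
    seeds = filter_cliques(cliques, params, gu, gw)
    grown = [
        grow_candidate(c, gu, gw, model, dynamic_neighborhood=params.dynamic_neighborhood)
        for c in seeds
    ]
    final = merge_filter(grown, params, gu, gw)
    final.sort(key=_rank_key)
    return ComplexCatalog(
        complexes=[c.members for c in final],
        names=[None] * len(final),
        scores=[c.score for c in final],
    )
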