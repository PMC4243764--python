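"""Gene Ontology parsing, annotation propagation and GO-based edge weighting.

The GO is a DAG of terms; annotation is transitive toward the root: a protein
annotated on a term is implicitly annotated on every ancestor reached through
``is_a`` and ``part_of`` edges.  The *annotation size* of a term is the number
of proteins annotated on it after this propagation, and the specificity of a
term is the ratio of its annotation size to the largest annotation size of any
term (``s_max``, attained at a root).

The semantic similarity between proteins p and q is

    sim(p, q) = -|C(p,q)| * log( min_{t in C(p,q)} size(t) / s_max )

where C(p,q) is the set of terms annotating both p and q.  Unannotated pairs
(or pairs sharing only the maximally-sized term) score 0.  The natural
logarithm is the default; the base is configurable.

The weighted PIN adds to each surviving edge the sum of this similarity and a
topological weight — the number of neighbors the two endpoints share in the
original network.  Edges whose GO similarity falls below a cutoff (0.9 by
default) are treated as likely false-positive interactions and removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger("pincomplex")

__all__ = [
    "GODag",
    "AnnotationMap",
    "OntologyStructureError",
    "GafParseError",
    "read_obo",
    "write_obo",
    "read_gaf",
    "write_gaf",
    "propagate_annotations",
    "semantic_similarity",
    "topological_weight",
    "build_weighted_network",
]

#: GO relationship types that carry annotation transitivity here.
TRANSITIVE_RELATIONS = ("is_a", "part_of")


class OntologyStructureError(ValueError):
    """Raised when the ontology is cyclic or references unknown terms."""


class GafParseError(ValueError):
    """Raised for malformed GAF rows."""


@dataclass
class GODag:
    """A parsed GO DAG: term IDs, parent links (is_a/part_of) and namespaces."""

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unresolved = {p for ps in self.parents.values() for p in ps} - self.terms
        if unresolved:
            raise OntologyStructureError(
                f"parent reference(s) to unloaded term(s): {sorted(unresolved)[:5]}"
            )
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            member = nx.find_cycle(g)[0][0]
            raise OntologyStructureError(f"ontology contains a cycle through {member}")

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of *term* (excluding the term itself), memoized."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.parents.get(term, ()):
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result


@dataclass
class AnnotationMap:
    """Protein → GO-term sets, direct and (after propagation) ancestor-closed.

    ``term_size`` and ``s_max`` are only populated by
    :func:`propagate_annotations`; the similarity of Eq.-style scoring needs
    the propagated form.
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, frozenset[str]] | None = None
    term_size: dict[str, int] = field(default_factory=dict)
    s_max: int = 0

    @property
    def is_propagated(self) -> bool:
        return self.propagated is not None

    def proteins(self) -> set[str]:
        return set(self.direct)


def read_obo(path: str | PathLike) -> GODag:
    """Load an OBO 1.2 ontology file.

    ``is_a`` and ``relationship: part_of`` become parent edges; obsolete terms
    are skipped; a cycle or an unresolved parent raises
    :class:`OntologyStructureError`.
    """
    multi = obonet.read_obo(path)
    terms = {n for n, d in multi.nodes(data=True) if d}  # attr-less nodes are dangling refs
    dangling = set(multi.nodes) - terms
    parents: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, rel in multi.edges(keys=True):
        if rel not in TRANSITIVE_RELATIONS:
            continue
        if parent in dangling or child in dangling:
            raise OntologyStructureError(f"edge {child} -{rel}-> {parent} references an unloaded term")
        parents[child].add(parent)
    namespace = {
        t: multi.nodes[t].get("namespace", "biological_process") for t in terms
    }
    return GODag(terms=terms, parents=parents, namespace=namespace)


def write_obo(dag: GODag, path: str | PathLike) -> None:
    """Write a minimal OBO 1.2 rendering of *dag* (round-trips with :func:`read_obo`)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: pincomplex-synthetic\n")
        for t in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {t}\n")
            fh.write(f"namespace: {dag.namespace.get(t, 'biological_process')}\n")
            for p in sorted(dag.parents.get(t, ())):
                fh.write(f"is_a: {p}\n")


def read_gaf(path: str | PathLike) -> AnnotationMap:
    """Read direct annotations from a GAF 2.x file (propagation pending).

    Maps the DB object symbol (column 3) to the GO ID (column 5); rows whose
    qualifier contains ``NOT`` are skipped, as are ``!``-prefixed headers.
    """
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("!") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise GafParseError(f"{path}:{lineno}: GAF row has {len(cols)} columns, expected >= 15")
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            symbol, go_id = cols[2], cols[4]
            direct.setdefault(symbol, set()).add(go_id)
    return AnnotationMap(direct=direct)


_GAF_FILLER = ["pincomplex", "", "", "", "", "GO_REF:0000000", "IEA", "", "P", "", "", "protein", "taxon:4932", "20140101", "pincomplex"]


def write_gaf(ann: AnnotationMap, path: str | PathLike) -> None:
    """Write direct annotations as a minimal GAF 2.2 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for protein in sorted(ann.direct):
            for term in sorted(ann.direct[protein]):
                row = list(_GAF_FILLER)
                row[1] = protein
                row[2] = protein
                row[4] = term
                fh.write("\t".join(row) + "\n")


def propagate_annotations(dag: GODag, ann: AnnotationMap) -> AnnotationMap:
    """Close every protein's annotation set over ancestors; recompute term sizes.

    Terms absent from *dag* are dropped with a warning.  ``term_size[t]`` is
    the number of proteins annotated on t after propagation and ``s_max`` the
    maximum over all terms (attained at some root by transitivity).
    """
    propagated: dict[str, frozenset[str]] = {}
    unknown: set[str] = set()
    for protein, terms in ann.direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag.terms:
                unknown.add(t)
                continue
            closed.add(t)
            closed |= dag.ancestors(t)
        propagated[protein] = frozenset(closed)
    if unknown:
        logger.warning("propagate_annotations: dropped %d annotation term(s) absent from the ontology", len(unknown))
    term_size: dict[str, int] = {}
    for terms in propagated.values():
        for t in terms:
            term_size[t] = term_size.get(t, 0) + 1
    s_max = max(term_size.values(), default=0)
    return AnnotationMap(
        direct={p: set(t) for p, t in ann.direct.items()},
        propagated=propagated,
        term_size=term_size,
        s_max=s_max,
    )


def semantic_similarity(
    p: str, q: str, ann: AnnotationMap, log_base: float | None = None
) -> float:
    """GO semantic similarity between two proteins (0 when unannotated/disjoint).

    Requires a propagated :class:`AnnotationMap`.  ``log_base=None`` means the
    natural logarithm.
    """
    if not ann.is_propagated:
        raise ValueError("semantic_similarity requires a propagated AnnotationMap")
    tp = ann.propagated.get(p)
    tq = ann.propagated.get(q)
    if not tp or not tq:
        return 0.0
    common = tp & tq
    if not common:
        return 0.0
    min_size = min(ann.term_size[t] for t in common)
    val = -len(common) * math.log(min_size / ann.s_max)
    if log_base is not None:
        val /= math.log(log_base)
    return max(val, 0.0)  # clamp -0.0 from log(1)


def topological_weight(graph: nx.Graph, u: str, v: str) -> int:
    """Number of neighbors shared by *u* and *v* (excluding u and v themselves)."""
    shared = set(graph.neighbors(u)) & set(graph.neighbors(v))
    shared.discard(u)
    shared.discard(v)
    return len(shared)


def build_weighted_network(
    graph: nx.Graph,
    ann: AnnotationMap,
    sim_cutoff: float = 0.9,
    log_base: float | None = None,
) -> tuple[nx.Graph, nx.Graph]:
    """Filter likely false-positive interactions and weight the survivors.

    Edges whose GO similarity is below *sim_cutoff* are removed (pairs with an
    unannotated endpoint score 0 and are removed too).  Returns the filtered
    unweighted graph and a weighted twin over the same edge set, where each
    edge weight is ``semantic_similarity + topological_weight``; the
    topological weight is counted on the original, pre-filter graph.  Node
    sets are left untouched (isolated nodes are permitted).
    """
    gu = nx.Graph()
    gu.add_nodes_from(graph.nodes)
    gw = nx.Graph()
    gw.add_nodes_from(graph.nodes)
    n_removed = 0
    for u, v in graph.edges:
        sim = semantic_similarity(u, v, ann, log_base=log_base)
        if sim < sim_cutoff:
            n_removed += 1
            continue
        w = sim + topological_weight(graph, u, v)
        gu.add_edge(u, v)
        gw.add_edge(u, v, weight=w)
    logger.info(
        "build_weighted_network: removed %d/%d edges below similarity %.3g",
        n_removed, graph.number_of_edges(), sim_cutoff,
    )
    return gu, gw
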