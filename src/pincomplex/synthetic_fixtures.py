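"""Synthetic benchmarks: planted complexes in a sparse PIN plus a coherent GO fixture.

The generator emulates the study conditions the detection method targets: a
sparse protein interaction network in which protein complexes appear as
planted dense subgraphs whose sizes follow a truncated power law, and a small
GO DAG whose annotations make co-complex proteins share a specific signature
term (so the GO-similarity edge filter is discriminative).

Each planted complex receives a dedicated leaf term in a balanced tree of
configurable depth; members are annotated on it with probability
``annotation_coherence``.  Background leaves, annotated uniformly at random,
add realistic annotation noise without aligning with the planted structure.
Within-complex node pairs are wired with probability ``p_in`` and all other
pairs with ``p_out``.  Complexes are node-disjoint by default so that
recovery metrics are unambiguous.

A companion helper converts a benchmark into the three-category training
bundle: a held-out split of the planted complexes, one-node-swap
perturbations standing in for another detector's near-miss predictions
(the "uncertainty" category), and random node sets as negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np

from .go_semantics import AnnotationMap, GODag
from .pin_io import ComplexCatalog
from .scoring_model import sample_negative_complexes

__all__ = [
    "BenchmarkSpec",
    "Benchmark",
    "TrainingBundle",
    "generate_benchmark",
    "generate_training_bundle",
]


@dataclass
class BenchmarkSpec:
    """Parameters of a synthetic planted-complex benchmark.

    Defaults describe the reference study condition used throughout the test
    suite: 500 proteins, 40 node-disjoint planted complexes with power-law
    sizes 3-10 (exponent 2), within-complex edge probability 0.9, background
    edge probability 0.005, a depth-3 GO tree with fully coherent signature
    annotation, and a 20% background annotation rate.
    """

    n_proteins: int = 500
    n_complexes: int = 40
    size_min: int = 3
    size_max: int = 10
    size_exponent: float = 2.0
    p_in: float = 0.9
    p_out: float = 0.005
    go_depth: int = 3
    annotation_coherence: float = 1.0
    background_annotation_rate: float = 0.2
    n_background_terms: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.size_min < 3 or self.size_max < self.size_min:
            raise ValueError("complex sizes must satisfy 3 <= size_min <= size_max")
        if not (0 <= self.annotation_coherence <= 1):
            raise ValueError("annotation_coherence must lie in [0, 1]")
        if self.go_depth < 1:
            raise ValueError("go_depth must be >= 1")


class Benchmark(NamedTuple):
    graph: nx.Graph
    complexes: ComplexCatalog
    dag: GODag
    annotations: AnnotationMap  # direct annotations; propagate before weighting
    spec: "BenchmarkSpec"


class TrainingBundle(NamedTuple):
    positives: ComplexCatalog
    intermediates: ComplexCatalog
    negatives: ComplexCatalog
    held_out: ComplexCatalog


def _power_law_sizes(spec: BenchmarkSpec, rng: np.random.Generator) -> list[int]:
    sizes = np.arange(spec.size_min, spec.size_max + 1)
    probs = sizes.astype(float) ** (-spec.size_exponent)
    probs /= probs.sum()
    return [int(s) for s in rng.choice(sizes, size=spec.n_complexes, p=probs)]


def _balanced_go_tree(n_leaves: int, depth: int) -> tuple[GODag, list[str]]:
    """Balanced b-ary tree with >= n_leaves leaves at the given depth; returns leaf IDs."""
    branching = max(2, math.ceil(n_leaves ** (1.0 / depth)))
    counter = 0

    def new_term() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    root = new_term()
    parents: dict[str, set[str]] = {root: set()}
    level = [root]
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                t = new_term()
                parents[t] = {parent}
                nxt.append(t)
        level = nxt
    dag = GODag(
        terms=set(parents),
        parents=parents,
        namespace={t: "biological_process" for t in parents},
    )
    return dag, level


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate a PIN with planted dense complexes and a matching GO fixture.

    Fully reproducible from ``spec.seed``.  Raises when the disjoint planted
    complexes cannot fit into ``n_proteins``.
    """
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    sizes = _power_law_sizes(spec, rng)
    if sum(sizes) > spec.n_proteins:
        raise ValueError(
            f"planted membership {sum(sizes)} exceeds {spec.n_proteins} proteins"
        )
    shuffled = list(rng.permutation(proteins))
    complexes: list[frozenset[str]] = []
    cursor = 0
    for s in sizes:
        complexes.append(frozenset(shuffled[cursor : cursor + s]))
        cursor += s
    member_of: dict[str, int] = {}
    for ci, cx in enumerate(complexes):
        for p in cx:
            member_of[p] = ci

    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    for cx in complexes:
        cs = sorted(cx)
        for a in range(len(cs)):
            for b in range(a + 1, len(cs)):
                if rng.random() < spec.p_in:
                    graph.add_edge(cs[a], cs[b])
    if spec.p_out > 0:
        # background: sample cross/non-complex pairs by index to stay O(E)
        n = spec.n_proteins
        n_pairs = n * (n - 1) // 2
        n_bg = rng.binomial(n_pairs, spec.p_out)
        for _ in range(n_bg):
            i, j = rng.integers(n), rng.integers(n)
            if i == j:
                continue
            u, v = proteins[i], proteins[j]
            if member_of.get(u) is not None and member_of.get(u) == member_of.get(v):
                continue  # within-complex wiring is governed by p_in only
            graph.add_edge(u, v)

    n_leaves = spec.n_complexes + spec.n_background_terms
    dag, leaves = _balanced_go_tree(n_leaves, spec.go_depth)
    signature = leaves[: spec.n_complexes]
    background = leaves[spec.n_complexes : spec.n_complexes + spec.n_background_terms]
    direct: dict[str, set[str]] = {}
    for ci, cx in enumerate(complexes):
        for p in sorted(cx):
            if rng.random() < spec.annotation_coherence:
                direct.setdefault(p, set()).add(signature[ci])
    if background:
        for p in proteins:
            if rng.random() < spec.background_annotation_rate:
                term = background[rng.integers(len(background))]
                direct.setdefault(p, set()).add(term)

    catalog = ComplexCatalog(complexes, [f"planted{i}" for i in range(len(complexes))])
    return Benchmark(graph, catalog, dag, AnnotationMap(direct=direct), spec)


def generate_training_bundle(
    benchmark: Benchmark,
    held_out_fraction: float = 0.5,
    n_negatives: int = 120,
    seed: int = 0,
) -> TrainingBundle:
    """Split the planted complexes and fabricate the three training categories.

    Positives are a seeded subset of the planted complexes (the rest are held
    out for evaluation); each positive is perturbed by one node swap to make
    an intermediate "uncertainty" sample; negatives are random node sets with
    the positive size distribution.
    """
    if not (0 < held_out_fraction < 1):
        raise ValueError("held_out_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(benchmark.complexes)
    order = list(rng.permutation(n))
    n_held = int(round(held_out_fraction * n))
    held_idx = sorted(order[:n_held])
    train_idx = sorted(order[n_held:])
    if not train_idx or not held_idx:
        raise ValueError("split leaves an empty partition; adjust held_out_fraction")
    positives = ComplexCatalog([benchmark.complexes[i] for i in train_idx])
    held_out = ComplexCatalog([benchmark.complexes[i] for i in held_idx])

    nodes = sorted(benchmark.graph.nodes)
    intermediates: list[frozenset[str]] = []
    for cx in positives:
        members = sorted(cx)
        drop = members[rng.integers(len(members))]
        while True:
            add = nodes[rng.integers(len(nodes))]
            if add not in cx:
                break
        intermediates.append(frozenset(set(cx) - {drop} | {add}))

    negatives = sample_negative_complexes(
        benchmark.graph,
        positives.sizes(),
        n_negatives,
        seed=(seed + 104729) % (2**31),
        exclusions=list(benchmark.complexes),
    )
    return TrainingBundle(
        positives,
        ComplexCatalog(intermediates),
        ComplexCatalog(negatives),
        held_out,
    )
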