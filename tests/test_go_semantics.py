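import math

import networkx as nx
import numpy as np
import pytest

from pincomplex import (
    AnnotationMap,
    GODag,
    build_weighted_network,
    propagate_annotations,
    read_gaf,
    read_obo,
    semantic_similarity,
    topological_weight,
    write_gaf,
    write_obo,
)
from pincomplex.go_semantics import GafParseError, OntologyStructureError


OBO_SMALL = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: child
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: grandchild via part_of
namespace: biological_process
relationship: part_of GO:0000002

[Term]
id: GO:0000009
name: obsolete term
is_obsolete: true
"""

GAF_HEADER = "!gaf-version: 2.2\n"


def gaf_row(symbol, term, qualifier="involved_in"):
    cols = ["DB", symbol, symbol, qualifier, term, "GO_REF:1", "IEA", "", "P", "", "",
            "protein", "taxon:4932", "20140101", "DB"]
    return "\t".join(cols) + "\n"


class TestReadObo:
    def test_parents_and_roots(self, tmp_path):
        p = tmp_path / "go.obo"
        p.write_text(OBO_SMALL)
        dag = read_obo(p)
        assert dag.terms == {"GO:0000001", "GO:0000002", "GO:0000003"}
        assert dag.parents["GO:0000002"] == {"GO:0000001"}
        assert dag.parents["GO:0000003"] == {"GO:0000002"}  # part_of is transitive here
        assert dag.roots == {"GO:0000001"}

    def test_obsolete_skipped(self, tmp_path):
        p = tmp_path / "go.obo"
        p.write_text(OBO_SMALL)
        assert "GO:0000009" not in read_obo(p).terms

    def test_cycle_detected(self):
        with pytest.raises(OntologyStructureError, match="cycle"):
            GODag(terms={"a", "b"}, parents={"a": {"b"}, "b": {"a"}})

    def test_unresolved_parent(self):
        with pytest.raises(OntologyStructureError, match="unloaded"):
            GODag(terms={"a"}, parents={"a": {"ghost"}})

    def test_write_read_round_trip(self, tmp_path):
        dag = GODag(
            terms={"GO:1", "GO:2", "GO:3"},
            parents={"GO:1": set(), "GO:2": {"GO:1"}, "GO:3": {"GO:1", "GO:2"}},
        )
        p = tmp_path / "rt.obo"
        write_obo(dag, p)
        back = read_obo(p)
        assert back.terms == dag.terms and back.parents == dag.parents


class TestReadGaf:
    def test_single_row(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(GAF_HEADER + gaf_row("P1", "GO:0000001"))
        assert read_gaf(p).direct == {"P1": {"GO:0000001"}}

    def test_not_qualifier_skipped(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(GAF_HEADER + gaf_row("P1", "GO:0000001", qualifier="NOT|involved_in"))
        assert read_gaf(p).direct == {}

    def test_duplicate_rows_collapse(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(GAF_HEADER + gaf_row("P1", "GO:0000001") * 2)
        assert read_gaf(p).direct == {"P1": {"GO:0000001"}}

    def test_short_row_rejected(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(GAF_HEADER + "too\tfew\tcolumns\n")
        with pytest.raises(GafParseError, match=":2"):
            read_gaf(p)

    def test_write_read_round_trip(self, tmp_path):
        ann = AnnotationMap(direct={"P1": {"GO:1", "GO:2"}, "P2": {"GO:1"}})
        p = tmp_path / "rt.gaf"
        write_gaf(ann, p)
        assert read_gaf(p).direct == ann.direct


def chain_dag(n):
    terms = [f"t{i}" for i in range(n)]
    parents = {terms[0]: set(), **{terms[i]: {terms[i - 1]} for i in range(1, n)}}
    return GODag(terms=set(terms), parents=parents), terms


class TestPropagation:
    def test_leaf_two_below_root(self):
        dag, terms = chain_dag(3)
        ann = propagate_annotations(dag, AnnotationMap(direct={"p": {terms[2]}}))
        assert ann.propagated["p"] == frozenset(terms)

    def test_root_only(self):
        dag, terms = chain_dag(3)
        ann = propagate_annotations(dag, AnnotationMap(direct={"p": {terms[0]}}))
        assert ann.propagated["p"] == frozenset({terms[0]})

    def test_diamond_counts_shared_ancestor_once(self):
        dag = GODag(
            terms={"r", "a", "b", "leaf"},
            parents={"r": set(), "a": {"r"}, "b": {"r"}, "leaf": {"a", "b"}},
        )
        ann = propagate_annotations(dag, AnnotationMap(direct={"p": {"leaf"}}))
        assert ann.propagated["p"] == frozenset({"r", "a", "b", "leaf"})
        assert ann.term_size["r"] == 1

    def test_unknown_terms_dropped(self):
        dag, terms = chain_dag(2)
        ann = propagate_annotations(dag, AnnotationMap(direct={"p": {terms[1], "ghost"}}))
        assert ann.propagated["p"] == frozenset(terms)

    def test_smax_is_a_root_size(self):
        dag, terms = chain_dag(4)
        direct = {f"p{i}": {terms[min(i, 3)]} for i in range(6)}
        ann = propagate_annotations(dag, AnnotationMap(direct=direct))
        assert ann.s_max == ann.term_size[terms[0]] == 6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_closure_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        terms = [f"t{i}" for i in range(n)]
        parents = {terms[0]: set()}
        for i in range(1, n):
            k = int(rng.integers(0, min(i, 3) + 1))
            parents[terms[i]] = set(rng.choice(terms[:i], size=k, replace=False)) if k else set()
        dag = GODag(terms=set(terms), parents=parents)
        direct = {}
        for p in range(8):
            k = int(rng.integers(1, 4))
            direct[f"p{p}"] = set(rng.choice(terms, size=k, replace=False))
        ann = propagate_annotations(dag, AnnotationMap(direct=direct))
        # oracle: iterate explicit parent expansion to a fixed point
        for prot, terms_direct in direct.items():
            closed = set(terms_direct)
            while True:
                grown = set(closed)
                for t in closed:
                    grown |= parents[t]
                if grown == closed:
                    break
                closed = grown
            assert ann.propagated[prot] == frozenset(closed)


def make_ann(direct, dag=None):
    if dag is None:
        terms = {t for ts in direct.values() for t in ts}
        dag = GODag(terms=terms, parents={t: set() for t in terms})
    return propagate_annotations(dag, AnnotationMap(direct=direct))


class TestSemanticSimilarity:
    def test_unannotated_protein_scores_zero(self):
        ann = make_ann({"p": {"t"}})
        assert semantic_similarity("p", "q", ann) == 0.0

    def test_root_only_shared_scores_zero(self):
        # both annotated only on the maximally-annotated term: log(1) = 0
        ann = make_ann({"p": {"r"}, "q": {"r"}})
        assert semantic_similarity("p", "q", ann) == 0.0

    def test_hand_computed_value(self):
        # |C(p,q)|=2 shared terms, min annotation size 10, s_max=100: 2*ln(10)
        direct = {}
        for i in range(10):
            direct[f"s{i}"] = {"tA", "tB"}
        for i in range(100):
            direct.setdefault(f"b{i}", set()).add("big")
        ann = make_ann(direct)
        assert ann.s_max == 100 and ann.term_size["tA"] == 10
        val = semantic_similarity("s0", "s1", ann)
        assert val == pytest.approx(2 * math.log(10), rel=1e-12)

    def test_log_base_conversion(self):
        direct = {f"s{i}": {"tA"} for i in range(10)}
        direct.update({f"b{i}": {"big"} for i in range(100)})
        ann = make_ann(direct)
        natural = semantic_similarity("s0", "s1", ann)
        base10 = semantic_similarity("s0", "s1", ann, log_base=10)
        assert base10 == pytest.approx(natural / math.log(10))

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(3)
        terms = [f"t{i}" for i in range(6)]
        direct = {
            f"p{i}": set(rng.choice(terms, size=int(rng.integers(1, 4)), replace=False))
            for i in range(10)
        }
        ann = make_ann(direct)
        prots = sorted(direct)
        for a in prots:
            for b in prots:
                s1, s2 = semantic_similarity(a, b, ann), semantic_similarity(b, a, ann)
                assert s1 == s2 >= 0.0

    def test_adding_annotation_never_shrinks_common_set(self):
        direct = {"p": {"tA"}, "q": {"tA", "tB"}}
        ann1 = make_ann(direct)
        c1 = ann1.propagated["p"] & ann1.propagated["q"]
        direct2 = {"p": {"tA", "tB"}, "q": {"tA", "tB"}}
        ann2 = make_ann(direct2)
        c2 = ann2.propagated["p"] & ann2.propagated["q"]
        assert c1 <= c2

    def test_requires_propagation(self):
        with pytest.raises(ValueError, match="propagated"):
            semantic_similarity("p", "q", AnnotationMap(direct={"p": {"t"}}))


class TestTopologicalWeight:
    def test_triangle_adjacent_pair(self, triangle):
        assert topological_weight(triangle, "a", "b") == 1

    def test_path_endpoints_share_middle(self):
        g = nx.path_graph(["a", "b", "c"])
        assert topological_weight(g, "a", "c") == 1

    def test_disjoint_edges_share_nothing(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert topological_weight(g, "a", "c") == 0


class TestBuildWeightedNetwork:
    def setup_method(self):
        # K4 on {a,b,c,d}: every adjacent pair shares the other 2 nodes
        self.g = nx.complete_graph(["a", "b", "c", "d"])

    def test_retained_edge_weight_is_sim_plus_topology(self):
        # all four proteins share one specific term -> identical sim per pair
        direct = {p: {"t"} for p in "abcd"}
        direct.update({f"x{i}": {"other"} for i in range(40)})  # s_max = 40
        ann = make_ann(direct)
        sim = semantic_similarity("a", "b", ann)
        assert sim == pytest.approx(math.log(10))  # -1*ln(4/40)
        gu, gw = build_weighted_network(self.g, ann, sim_cutoff=0.9)
        assert set(gu.edges) == set(self.g.edges)
        assert gw["a"]["b"]["weight"] == pytest.approx(sim + 2)

    def test_low_similarity_edges_removed_everywhere(self):
        ann = make_ann({p: {"r"} for p in "abcd"})  # only the root shared: sim 0
        gu, gw = build_weighted_network(self.g, ann, sim_cutoff=0.9)
        assert gu.number_of_edges() == 0 == gw.number_of_edges()
        assert set(gu.nodes) == set(self.g.nodes)

    def test_unannotated_pair_removed(self):
        ann = make_ann({"a": {"t"}, "other": {"t"}})
        gu, _ = build_weighted_network(self.g, ann)
        assert gu.number_of_edges() == 0

    def test_filtered_edges_subset_and_nodes_unchanged(self, benchmark_small):
        bench, ann, gu, gw = benchmark_small
        assert set(gu.edges) <= set(bench.graph.edges)
        assert set(gu.nodes) == set(bench.graph.nodes)
        assert set(gu.edges) == set(gw.edges)
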