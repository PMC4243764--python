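import networkx as nx
import numpy as np
import pytest

import pincomplex as pc


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


@pytest.fixture
def triangle_w() -> nx.Graph:
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    return g


def random_graph(rng: np.random.Generator, n: int, density: float) -> nx.Graph:
    """Erdős–Rényi graph over string node labels, reproducible from *rng*."""
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                g.add_edge(nodes[i], nodes[j])
    return g


@pytest.fixture(scope="session")
def benchmark_small():
    """A compact planted-complex benchmark shared by pipeline-level tests."""
    spec = pc.BenchmarkSpec(n_proteins=120, n_complexes=8, size_max=8, seed=7)
    bench = pc.generate_benchmark(spec)
    ann = pc.propagate_annotations(bench.dag, bench.annotations)
    gu, gw = pc.build_weighted_network(bench.graph, ann)
    return bench, ann, gu, gw
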