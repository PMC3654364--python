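import numpy as np
import pytest

from hopemap import (
    AlignmentGraph,
    AlignmentNode,
    BenchmarkConfig,
    Namespace,
    align,
    generate_benchmark,
    ko_annotation_from_homologs,
)


def make_graph(n, edges, species=("spA", "spB")):
    """Alignment graph with n dummy nodes and the given undirected edges."""
    nodes = [
        AlignmentNode(
            node_id=i,
            members={sp: f"{sp}_x{i}" for sp in species},
            group_id=f"G{i}",
        )
        for i in range(n)
    ]
    graph = AlignmentGraph(nodes=nodes)
    for u, v in edges:
        graph.add_edge(u, v, {sp: "direct" for sp in species})
    return graph


def random_graph(rng, max_n=40, max_p=0.2):
    n = int(rng.integers(1, max_n + 1))
    p = float(rng.uniform(0, max_p))
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return make_graph(n, edges)


@pytest.fixture
def graph_factory():
    return make_graph


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free study conditions: every planted module must be recovered
    perfectly."""
    return BenchmarkConfig(
        n_species=2,
        n_proteins=60,
        n_modules=3,
        module_size=4,
        module_topology="clique",
        background_edge_prob=0.0,
        conserved_edge_dropout=0.0,
        n_decoy_groups=5,
        annotation_noise=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_benchmark(clean_config):
    return generate_benchmark(clean_config)


@pytest.fixture(scope="session")
def clean_alignment(clean_benchmark):
    """(benchmark, graph, clusters) for the noise-free conditions."""
    graph, clusters = align(clean_benchmark.networks, clean_benchmark.homologs)
    return clean_benchmark, graph, clusters


@pytest.fixture(scope="session")
def noisy_benchmark():
    """Default study conditions (dropout, background edges, noise)."""
    return generate_benchmark(BenchmarkConfig(seed=3))


@pytest.fixture
def ko_from_table():
    return lambda bench: ko_annotation_from_homologs(bench.homologs)
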