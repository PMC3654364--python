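"""HopeMap-style global alignment of protein-protein interaction networks.

Pairwise (and three-way) PPI networks are aligned through a cross-species
alignment graph built from precompiled homolog groups; conserved regions
are its connected components, scored by genomic similarity, interaction
conservation and functional coherence, refined by iterative
connected-components finding (ICCF), and validated against KO, GO and MIPS
annotations.
"""

from .io_formats import (
    AnnotationMap,
    HomologGroupTable,
    Namespace,
    ParseError,
    PPINetwork,
    SimilarityTable,
    read_annotations,
    read_blast_tabular,
    read_clusters,
    read_homolog_groups,
    read_ppi_network,
    write_clusters,
)
from .alignment_graph import (
    AlignmentGraph,
    AlignmentNode,
    add_edges_multiway,
    add_edges_pairwise,
    build_nodes,
    interaction_universe,
    read_alignment_graph,
    write_alignment_graph,
)
from .components import (
    Cluster,
    ICCFResult,
    connected_components,
    filter_by_size,
    iccf,
)
from .scoring import (
    ClusterScore,
    ScoringInputs,
    SignificanceResult,
    combined_score,
    compute_node_confidences,
    empirical_pvalue,
    functional_coherence,
    interaction_conservation,
    node_confidence_blast,
    node_confidence_ortholog,
    normalize_over_clusters,
    score_clusters,
    sequence_similarity_score,
    significance_scores,
)
from .evaluation import (
    EnrichmentResult,
    EvaluationReport,
    evaluate,
    go_enrichment,
    go_specificity_sensitivity,
    ko_annotation_from_homologs,
    ko_sensitivity,
    ko_specificity,
    mips_coverage,
)
from .benchmark import (
    Benchmark,
    BenchmarkConfig,
    GroundTruth,
    RecoveryResult,
    generate_benchmark,
    recovery_metrics,
    write_benchmark,
)

__version__ = "0.1.0"


def align(
    networks,
    homologs,
    mode: str = "group_all_pairs",
    similarity=None,
    min_direct: int = 2,
    max_indirect_distance: int = 2,
    min_cluster_size: int = 2,
):
    """One-call alignment: build nodes and edges, return (graph, clusters).

    Pairwise (2 networks) uses the direct-conservation edge rule; three-way
    uses the relaxed rule (``min_direct`` species direct, the rest within
    ``max_indirect_distance`` hops).  Clusters smaller than
    ``min_cluster_size`` are dropped from the returned list.
    """
    nodes = build_nodes(homologs, networks, mode=mode, similarity=similarity)
    if len(networks) == 2:
        graph = add_edges_pairwise(nodes, networks)
    elif len(networks) == 3:
        graph = add_edges_multiway(
            nodes, networks,
            min_direct=min_direct,
            max_indirect_distance=max_indirect_distance,
        )
    else:
        raise ValueError("alignment needs exactly 2 or 3 networks")
    clusters = filter_by_size(connected_components(graph), min_cluster_size)
    return graph, clusters


__all__ = [name for name in dir() if not name.startswith("_")]
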