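"""Cluster scoring: genomic similarity S(C), interaction conservation I(C),
functional coherence F(C), the combined score, and empirical significance.

The combined score of a cluster C is

    Score(C) = w1*S(C) + w2*I(C) + w3*F(C),        w1 = w2 = w3 = 1/3

with every component in [0, 1], so scores of different clusters are directly
comparable.  S averages per-node homology confidence (BLAST e-value based,
or a 0/1 ortholog-annotation indicator); I is the cliqueness ratio
i(C) / (|C|(|C|-1)/2), normalized over all clusters; F is the
intersection-over-union of GO biological-process term sets per species,
averaged over species.

Significance is empirical: N random node subsets of the same size are drawn
from the alignment graph, each component is recomputed on them, and
p = (R + 1)/(N + 1) where R counts null samples at or above the observed
value.  A significance-weighted combination sums the three (R_i+1)/(N_i+1)
terms; note it runs opposite in direction to the combined score (smaller is
more significant), so it is reported alongside, not blended in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .alignment_graph import AlignmentGraph, AlignmentNode
from .components import Cluster
from .io_formats import AnnotationMap, Namespace, PPINetwork, SimilarityTable

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
MIN_NULL_SAMPLES = 100
DEFAULT_NULL_SAMPLES = 3000  # null ensembles of 3000-5000 are ample


@dataclass
class ClusterScore:
    S: float
    s_k: dict[int, float]
    I_raw: Optional[float]  # None for singleton clusters (not scorable)
    I_norm: float
    F: float
    weights: tuple[float, float, float]
    score: float


@dataclass
class SignificanceResult:
    p_S: float
    p_I: float
    p_F: float
    N_S: int
    N_I: int
    N_F: int
    R_S: int
    R_I: int
    R_F: int
    combined_eq5: float
    seed: int


@dataclass
class ScoringInputs:
    """Everything score computation needs besides the clusters themselves.

    ``confidences`` maps every alignment-node id to its homology confidence
    s(k) in [0, 1].  Normalization-over-clusters is mandatory for I and
    optional for S and F.
    """

    confidences: dict[int, float]
    annotations: Optional[AnnotationMap] = None
    networks: Sequence[PPINetwork] = ()
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    normalize_S: bool = False
    normalize_I: bool = True
    normalize_F: bool = False


# ---------------------------------------------------------------------------
# Node confidences
# ---------------------------------------------------------------------------


def _node_e_value(
    node: AlignmentNode, similarity: SimilarityTable
) -> Optional[float]:
    """Cross-species e-value of a node: the pair's e-value for two species,
    the geometric mean over species pairs for three."""
    proteins = [node.members[sp] for sp in sorted(node.members)]
    log_sum = 0.0
    n_pairs = 0
    for a, b in combinations(proteins, 2):
        e_value = similarity.e_value(a, b)
        if e_value is None:
            return None
        log_sum += math.log(e_value)
        n_pairs += 1
    if n_pairs == 0:
        return None
    return math.exp(log_sum / n_pairs)


def node_confidence_blast(
    node: AlignmentNode,
    cluster_nodes: Sequence[AlignmentNode],
    similarity: SimilarityTable,
) -> float:
    """BLAST-based confidence of one node within its cluster.

    With Ebar the arithmetic mean of the cluster's node e-values: 1 if the
    node's e-value is at most Ebar, else Ebar divided by the node's e-value
    (smaller e-values mean stronger homology, so this lands in [0, 1]).
    Nodes with no similarity record get confidence 0.
    """
    node_e = _node_e_value(node, similarity)
    if node_e is None:
        logger.warning("node %d: missing similarity record; confidence 0", node.node_id)
        return 0.0
    cluster_es = [
        e for e in (_node_e_value(n, similarity) for n in cluster_nodes)
        if e is not None
    ]
    if not cluster_es:
        return 0.0
    mean_e = sum(cluster_es) / len(cluster_es)
    if node_e <= mean_e:
        return 1.0
    return mean_e / node_e


def node_confidence_ortholog(node: AlignmentNode, ko: AnnotationMap) -> float:
    """1 if all the node's member proteins share at least one KO (ortholog)
    term, else 0."""
    if ko.namespace is not Namespace.KO:
        raise ValueError(f"ortholog confidence needs KO annotations, got {ko.namespace}")
    shared: Optional[set[str]] = None
    for protein in node.members.values():
        terms = ko.terms_for(protein)
        shared = set(terms) if shared is None else shared & terms
        if not shared:
            return 0.0
    return 1.0 if shared else 0.0


def compute_node_confidences(
    clusters: Sequence[Cluster],
    graph: AlignmentGraph,
    mode: str = "ortholog",
    similarity: Optional[SimilarityTable] = None,
    ko: Optional[AnnotationMap] = None,
) -> dict[int, float]:
    """Per-node s(k) for every node appearing in ``clusters``.

    BLAST-mode confidence is cluster-relative (the averaging baseline is the
    node's own cluster); ortholog-mode confidence is intrinsic to the node.
    """
    confidences: dict[int, float] = {}
    if mode == "blast":
        if similarity is None:
            raise ValueError("blast confidence mode requires a similarity table")
        for cluster in clusters:
            members = [graph.node_by_id(i) for i in sorted(cluster.node_ids)]
            for node in members:
                confidences[node.node_id] = node_confidence_blast(
                    node, members, similarity
                )
    elif mode == "ortholog":
        if ko is None:
            raise ValueError("ortholog confidence mode requires KO annotations")
        for cluster in clusters:
            for node_id in cluster.node_ids:
                confidences[node_id] = node_confidence_ortholog(
                    graph.node_by_id(node_id), ko
                )
    else:
        raise ValueError(f"unknown confidence mode {mode!r}")
    return confidences


# ---------------------------------------------------------------------------
# Score components
# ---------------------------------------------------------------------------


def sequence_similarity_score(
    cluster: Cluster, confidences: dict[int, float]
) -> float:
    """S(C): mean node confidence, sum_k s(k) / |C|."""
    if cluster.size == 0:
        raise ValueError("cannot score an empty cluster")
    try:
        total = sum(confidences[node_id] for node_id in cluster.node_ids)
    except KeyError as missing:
        raise ValueError(f"no confidence for node {missing.args[0]}") from None
    return total / cluster.size


def interaction_conservation(cluster: Cluster) -> Optional[float]:
    """I(C) before normalization: i(C) / (|C|(|C|-1)/2), the fraction of the
    clique's edges actually conserved.  Singletons are not scorable (None)."""
    if cluster.size < 2:
        return None
    cliqueness = cluster.size * (cluster.size - 1) // 2
    return cluster.edge_count / cliqueness


def normalize_over_clusters(values: Sequence[float]) -> list[float]:
    """Across-cluster normalization: values above the mean become 1.0, the
    rest become value / mean (so the mean itself maps to 1.0)."""
    if len(values) == 0:
        raise ValueError("cannot normalize an empty list")
    if any(v < 0 for v in values):
        raise ValueError("normalization expects non-negative values")
    mean = sum(values) / len(values)
    if mean == 0.0:
        logger.warning("normalization mean is 0; all values map to 0")
        return [0.0 for _ in values]
    return [1.0 if v >= mean else v / mean for v in values]


def functional_coherence(
    cluster_node_ids,
    graph: AlignmentGraph,
    annotations: AnnotationMap,
    networks: Sequence[PPINetwork],
) -> float:
    """F(C): per species, intersection-over-union of the GO biological
    process term sets of the cluster's annotated member proteins, averaged
    over species.

    Unannotated proteins contribute to neither numerator nor denominator; a
    species needs at least two annotated member proteins to count, and F is
    0 when every species is skipped.
    """
    if annotations.namespace is not Namespace.GO_BP:
        raise ValueError(
            f"functional coherence needs GO_BP annotations, got {annotations.namespace}"
        )
    species_ids = [net.species_id for net in networks]
    ratios = []
    for sp in species_ids:
        term_sets = []
        for node_id in cluster_node_ids:
            protein = graph.node_by_id(node_id).members.get(sp)
            if protein is None:
                continue
            terms = annotations.terms_for(protein)
            if terms:
                term_sets.append(terms)
        if len(term_sets) < 2:
            continue
        union = set().union(*term_sets)
        inter = set(term_sets[0])
        for terms in term_sets[1:]:
            inter &= terms
        ratios.append(len(inter) / len(union))
    if not ratios:
        return 0.0
    return sum(ratios) / len(ratios)


def combined_score(
    S: float,
    I_norm: float,
    F: float,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Score(C) = w1*S + w2*I + w3*F with non-negative weights summing to 1."""
    w1, w2, w3 = weights
    if min(w1, w2, w3) < 0:
        raise ValueError("weights must be non-negative")
    if abs(w1 + w2 + w3 - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w1 + w2 + w3}")
    for name, value in (("S", S), ("I", I_norm), ("F", F)):
        if not 0.0 <= value <= 1.0 + 1e-12:
            raise ValueError(f"component {name}={value} outside [0, 1]")
    return w1 * S + w2 * I_norm + w3 * F


def score_clusters(
    clusters: Sequence[Cluster],
    graph: AlignmentGraph,
    inputs: ScoringInputs,
) -> list[ClusterScore]:
    """Score every cluster; I is normalized across the scorable (size >= 2)
    clusters of this batch, so scores are batch-relative by design.

    Singleton clusters get I_raw = None and contribute I = 0 to the combined
    score (they conserve no interaction).
    """
    S_values = [
        sequence_similarity_score(c, inputs.confidences) for c in clusters
    ]
    I_raw = [interaction_conservation(c) for c in clusters]
    if inputs.annotations is not None:
        F_values = [
            functional_coherence(
                sorted(c.node_ids), graph, inputs.annotations, inputs.networks
            )
            for c in clusters
        ]
    else:
        F_values = [0.0 for _ in clusters]

    scorable = [v for v in I_raw if v is not None]
    if scorable:
        normalized = iter(normalize_over_clusters(scorable))
        I_norm = [0.0 if v is None else next(normalized) for v in I_raw]
    else:
        I_norm = [0.0 for _ in I_raw]
    S_eff = normalize_over_clusters(S_values) if (inputs.normalize_S and clusters) else S_values
    F_eff = normalize_over_clusters(F_values) if (inputs.normalize_F and clusters) else F_values

    scores = []
    for idx, cluster in enumerate(clusters):
        scores.append(
            ClusterScore(
                S=S_values[idx],
                s_k={i: inputs.confidences[i] for i in sorted(cluster.node_ids)},
                I_raw=I_raw[idx],
                I_norm=I_norm[idx],
                F=F_values[idx],
                weights=inputs.weights,
                score=combined_score(
                    S_eff[idx], I_norm[idx], F_eff[idx], inputs.weights
                ),
            )
        )
    return scores


# ---------------------------------------------------------------------------
# Empirical significance
# ---------------------------------------------------------------------------


def empirical_pvalue(actual: float, null_values: Sequence[float]) -> float:
    """(R + 1)/(N + 1) with R the number of null values >= the observation."""
    n = len(null_values)
    if n == 0:
        raise ValueError("empirical p-value needs a non-empty null sample")
    r = sum(1 for v in null_values if v >= actual)
    return (r + 1) / (n + 1)


def significance_scores(
    cluster: Cluster,
    graph: AlignmentGraph,
    inputs: ScoringInputs,
    N: int = DEFAULT_NULL_SAMPLES,
    seed: int = 0,
) -> SignificanceResult:
    """Empirical p-values for S, I and F of one cluster.

    The null draws N uniformly random node subsets of size |C| from the
    alignment graph (not connected subgraphs: connectivity is exactly what
    the I-statistic is meant to detect) and recomputes each component on
    them, reusing the per-node confidences in ``inputs``.
    """
    if N < MIN_NULL_SAMPLES:
        raise ValueError(f"need at least {MIN_NULL_SAMPLES} null samples, got {N}")
    if cluster.size < 2:
        raise ValueError("significance is defined for clusters of size >= 2")
    node_ids = np.array(sorted(graph.adjacency()), dtype=np.int64)
    if cluster.size > len(node_ids):
        raise ValueError(
            f"cluster size {cluster.size} exceeds graph size {len(node_ids)}"
        )
    rng = np.random.default_rng(seed)
    adjacency = graph.adjacency()

    actual_S = sequence_similarity_score(cluster, inputs.confidences)
    actual_I = interaction_conservation(cluster)
    actual_F = (
        functional_coherence(
            sorted(cluster.node_ids), graph, inputs.annotations, inputs.networks
        )
        if inputs.annotations is not None
        else 0.0
    )

    cliqueness = cluster.size * (cluster.size - 1) / 2
    null_S = np.empty(N)
    null_I = np.empty(N)
    null_F = np.empty(N)
    for i in range(N):
        subset = rng.choice(node_ids, size=cluster.size, replace=False)
        subset_set = set(int(x) for x in subset)
        null_S[i] = (
            sum(inputs.confidences.get(n, 0.0) for n in subset_set) / cluster.size
        )
        edges = 0
        for u in subset_set:
            edges += sum(1 for w in adjacency[u] if w > u and w in subset_set)
        null_I[i] = edges / cliqueness
        null_F[i] = (
            functional_coherence(
                sorted(subset_set), graph, inputs.annotations, inputs.networks
            )
            if inputs.annotations is not None
            else 0.0
        )

    R_S = int(np.sum(null_S >= actual_S))
    R_I = int(np.sum(null_I >= actual_I))
    R_F = int(np.sum(null_F >= actual_F))
    w1, w2, w3 = inputs.weights
    combined = (
        w1 * (R_S + 1) / (N + 1) + w2 * (R_I + 1) / (N + 1) + w3 * (R_F + 1) / (N + 1)
    )
    return SignificanceResult(
        p_S=(R_S + 1) / (N + 1),
        p_I=(R_I + 1) / (N + 1),
        p_F=(R_F + 1) / (N + 1),
        N_S=N, N_I=N, N_F=N,
        R_S=R_S, R_I=R_I, R_F=R_F,
        combined_eq5=combined,
        seed=seed,
    )
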