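"""Validation metrics for an alignment run.

KO-based specificity treats each alignment node as an equivalence class: a
node is correct when all its member proteins share at least one KO term.
Ceq is the fraction of correct classes and Cnode the fraction of nodes in
correct classes (with single-node classes the two coincide).  Sensitivity
counts correct nodes (Cor) against the number of homolog groups eligible
for alignment (Tot).  GO-based metrics use a hypergeometric enrichment test
with Benjamini-Hochberg FDR control: a cluster is process-coherent in a
species when at least one biological-process term is enriched in its
projected protein set at adjusted p < alpha.  No GO-DAG term propagation is
performed; annotations are taken exactly as given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .alignment_graph import AlignmentGraph, AlignmentNode
from .components import Cluster
from .io_formats import AnnotationMap, HomologGroupTable, Namespace, PPINetwork

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class EnrichmentResult:
    term: str
    k: int       # cluster proteins carrying the term
    K: int       # background proteins carrying the term
    n: int       # annotated cluster proteins
    M: int       # background size
    p_raw: float
    p_adj: float


@dataclass
class EvaluationReport:
    Ceq: float
    Cnode: float
    Cor: int
    Tot: int
    per_species_go_specificity: dict[str, float] = field(default_factory=dict)
    go_categories_enriched: int = 0
    mips_complex_coverage: Optional[float] = None
    mips_funcat_coverage: Optional[float] = None
    specificity_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "Ceq": self.Ceq,
            "Cnode": self.Cnode,
            "Cor": self.Cor,
            "Tot": self.Tot,
            "per_species_go_specificity": dict(self.per_species_go_specificity),
            "go_categories_enriched": self.go_categories_enriched,
            "mips_complex_coverage": self.mips_complex_coverage,
            "mips_funcat_coverage": self.mips_funcat_coverage,
            "specificity_defined": self.specificity_defined,
        }


# ---------------------------------------------------------------------------
# KO metrics
# ---------------------------------------------------------------------------


def ko_annotation_from_homologs(homologs: HomologGroupTable) -> AnnotationMap:
    """KO annotations read off a KO-style group table: each protein is
    annotated with the ids of the groups it belongs to.  When alignment
    nodes are built from the same table, every node's members share its
    originating group id, so Ceq = Cnode = 1 identically."""
    annotation = AnnotationMap(namespace=Namespace.KO)
    for group_id, per_species in homologs.groups.items():
        for members in per_species.values():
            for protein in members:
                annotation.add(protein, group_id)
    return annotation


def node_is_correct(node: AlignmentNode, ko: AnnotationMap) -> bool:
    """An equivalence class (node) is correct iff all member proteins share
    at least one KO term."""
    shared: Optional[set[str]] = None
    for protein in node.members.values():
        terms = ko.terms_for(protein)
        shared = set(terms) if shared is None else shared & terms
        if not shared:
            return False
    return bool(shared)


def ko_specificity(
    clusters: Sequence[Cluster], graph: AlignmentGraph, ko: AnnotationMap
) -> tuple[float, float]:
    """(Ceq, Cnode) over all nodes appearing in the reported clusters.

    Classes are single alignment nodes, so a node is "in a correct class"
    exactly when it is itself correct and the two fractions coincide; both
    are computed literally for transparency.
    """
    node_ids = sorted({n for c in clusters for n in c.node_ids})
    if not node_ids:
        raise ValueError("KO specificity needs at least one clustered node")
    correct = {
        node_id
        for node_id in node_ids
        if node_is_correct(graph.node_by_id(node_id), ko)
    }
    ceq = len(correct) / len(node_ids)
    in_correct_class = sum(1 for node_id in node_ids if node_id in correct)
    cnode = in_correct_class / len(node_ids)
    return ceq, cnode


def ko_sensitivity(
    clusters: Sequence[Cluster],
    graph: AlignmentGraph,
    ko: AnnotationMap,
    homologs: HomologGroupTable,
    networks: Sequence[PPINetwork],
) -> tuple[int, int]:
    """(Cor, Tot): correct clustered nodes vs. alignable homolog groups.

    A group counts toward Tot when every aligned species has at least one
    member present in its PPI network.
    """
    node_ids = sorted({n for c in clusters for n in c.node_ids})
    cor = sum(
        1 for node_id in node_ids if node_is_correct(graph.node_by_id(node_id), ko)
    )
    present = {net.species_id: net.proteins for net in networks}
    tot = 0
    for group_id, per_species in homologs.groups.items():
        if all(
            any(p in present[sp] for p in per_species.get(sp, []))
            for sp in present
        ):
            tot += 1
    return cor, tot


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------


def go_enrichment(
    cluster_proteins: set[str],
    background: set[str],
    annotations: AnnotationMap,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test with BH-FDR correction.

    For each term with at least one cluster hit, the upper-tail probability
    of observing >= k annotated cluster proteins given K background carriers
    among M background proteins, with n the number of annotated cluster
    proteins drawn.  Results are sorted by adjusted p, then term id.
    """
    if not cluster_proteins <= background:
        raise ValueError("cluster proteins must be a subset of the background")
    if len(background) < len(cluster_proteins):
        raise ValueError("background smaller than the cluster")
    M = len(background)
    annotated_cluster = [
        p for p in cluster_proteins if annotations.terms_for(p)
    ]
    n = len(annotated_cluster)
    if n == 0:
        return []
    term_hits: dict[str, int] = {}
    for protein in annotated_cluster:
        for term in annotations.terms_for(protein):
            term_hits[term] = term_hits.get(term, 0) + 1
    background_hits = {term: 0 for term in term_hits}
    for protein in background:
        for term in annotations.terms_for(protein):
            if term in background_hits:
                background_hits[term] += 1
    terms = sorted(term_hits)
    p_raw = [
        float(hypergeom.sf(term_hits[t] - 1, M, background_hits[t], n))
        for t in terms
    ]
    if p_raw:
        _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    else:
        p_adj = []
    results = [
        EnrichmentResult(
            term=t,
            k=term_hits[t],
            K=background_hits[t],
            n=n,
            M=M,
            p_raw=p_raw[i],
            p_adj=float(p_adj[i]),
        )
        for i, t in enumerate(terms)
    ]
    results.sort(key=lambda r: (r.p_adj, r.term))
    return results


def go_specificity_sensitivity(
    clusters: Sequence[Cluster],
    graph: AlignmentGraph,
    annotations: AnnotationMap,
    networks: Sequence[PPINetwork],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[str, float], int, bool]:
    """Per-species process-coherence specificity and GO-category sensitivity.

    Specificity per species: fraction of clusters whose projected protein
    set has >= 1 biological-process term with adjusted p < alpha against the
    species' full network as background.  Sensitivity: number of distinct
    enriched terms across all clusters and species.  The trailing flag is
    False when there are no clusters (specificity undefined).
    """
    if annotations.namespace is not Namespace.GO_BP:
        raise ValueError(
            f"GO specificity needs GO_BP annotations, got {annotations.namespace}"
        )
    if not clusters:
        return {net.species_id: 0.0 for net in networks}, 0, False
    specificity: dict[str, float] = {}
    enriched_terms: set[str] = set()
    for network in networks:
        background = set(network.proteins)
        coherent = 0
        for cluster in clusters:
            projected = {
                graph.node_by_id(node_id).members[network.species_id]
                for node_id in cluster.node_ids
                if network.species_id in graph.node_by_id(node_id).members
            }
            projected &= background
            results = go_enrichment(projected, background, annotations, alpha)
            hits = [r for r in results if r.p_adj < alpha]
            if hits:
                coherent += 1
                enriched_terms.update(r.term for r in hits)
        specificity[network.species_id] = coherent / len(clusters)
    return specificity, len(enriched_terms), True


def mips_coverage(
    clusters: Sequence[Cluster],
    graph: AlignmentGraph,
    complexes: AnnotationMap,
    species_id: Optional[str] = None,
) -> float:
    """Fraction of clusters whose member proteins all share >= 1 MIPS
    complex (or FunCat) term; an unannotated member leaves the cluster
    uncovered.  ``species_id`` restricts assessment to one species' members.
    """
    if complexes.namespace not in (Namespace.MIPS_COMPLEX, Namespace.MIPS_FUNCAT):
        raise ValueError(
            f"MIPS coverage needs a MIPS namespace, got {complexes.namespace}"
        )
    if not clusters:
        return 0.0
    covered = 0
    for cluster in clusters:
        shared: Optional[set[str]] = None
        for node_id in sorted(cluster.node_ids):
            members = graph.node_by_id(node_id).members
            proteins = (
                [members[species_id]] if species_id is not None and species_id in members
                else (list(members.values()) if species_id is None else [])
            )
            for protein in proteins:
                terms = complexes.terms_for(protein)
                shared = set(terms) if shared is None else shared & terms
        if shared:
            covered += 1
    return covered / len(clusters)


def evaluate(
    clusters: Sequence[Cluster],
    graph: AlignmentGraph,
    ko: AnnotationMap,
    homologs: HomologGroupTable,
    networks: Sequence[PPINetwork],
    go_bp: Optional[AnnotationMap] = None,
    mips_complex: Optional[AnnotationMap] = None,
    mips_funcat: Optional[AnnotationMap] = None,
    alpha: float = DEFAULT_ALPHA,
) -> EvaluationReport:
    """Full evaluation report for one alignment run."""
    if clusters:
        ceq, cnode = ko_specificity(clusters, graph, ko)
    else:
        ceq = cnode = 0.0
    cor, tot = ko_sensitivity(clusters, graph, ko, homologs, networks)
    if go_bp is not None:
        specificity, enriched, defined = go_specificity_sensitivity(
            clusters, graph, go_bp, networks, alpha
        )
    else:
        specificity, enriched, defined = {}, 0, False
    report = EvaluationReport(
        Ceq=ceq,
        Cnode=cnode,
        Cor=cor,
        Tot=tot,
        per_species_go_specificity=specificity,
        go_categories_enriched=enriched,
        specificity_defined=defined and bool(clusters),
    )
    if mips_complex is not None:
        report.mips_complex_coverage = mips_coverage(clusters, graph, mips_complex)
    if mips_funcat is not None:
        report.mips_funcat_coverage = mips_coverage(clusters, graph, mips_funcat)
    return report
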