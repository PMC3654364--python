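"""Conserved regions as connected components, plus the ICCF refinement loop.

The component finder is Tarjan's lowlink algorithm run on the symmetrized
arc set (each undirected edge as two arcs).  On a symmetric relation the
strongly connected components coincide with the connected components, so
this is faithful to the classic SCC formulation while an independent
flood-fill oracle (used only in tests) guards correctness.  The DFS uses an
explicit work stack, so component size is not limited by the interpreter
recursion limit, and nodes are visited in ascending node id, making cluster
ids deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .alignment_graph import AlignmentGraph


@dataclass(frozen=True)
class Cluster:
    """A connected component of the alignment graph.

    ``edge_count`` is i(C), the number of alignment-graph edges with both
    endpoints inside the cluster; ``size`` is |C|.
    """

    cluster_id: int
    node_ids: frozenset[int]
    edge_count: int
    size: int

    def __post_init__(self):
        if self.size < 1 or self.size != len(self.node_ids):
            raise ValueError("cluster size must equal |node_ids| and be >= 1")


@dataclass
class ICCFResult:
    clusters: list[Cluster]
    iterations: int
    removed_per_iteration: list[int]
    converged: bool


def _clusters_from_partition(
    partition: list[list[int]], graph: AlignmentGraph
) -> list[Cluster]:
    """Assemble Cluster objects, counting intra-cluster edges in one pass."""
    component_of: dict[int, int] = {}
    for idx, nodes in enumerate(partition):
        for node_id in nodes:
            component_of[node_id] = idx
    edge_counts = [0] * len(partition)
    for u, v in graph.edges:
        cu = component_of.get(u)
        if cu is not None and cu == component_of.get(v):
            edge_counts[cu] += 1
    return [
        Cluster(
            cluster_id=idx,
            node_ids=frozenset(nodes),
            edge_count=edge_counts[idx],
            size=len(nodes),
        )
        for idx, nodes in enumerate(partition)
    ]


def connected_components(graph: AlignmentGraph) -> list[Cluster]:
    """Partition the alignment graph into maximal connected clusters.

    Iterative Tarjan on symmetrized arcs; clusters are ordered (and ids
    assigned) by the discovery index of their earliest-visited node.
    """
    adj = {u: sorted(nbrs) for u, nbrs in graph.adjacency().items()}
    index: dict[int, int] = {}
    lowlink: dict[int, int] = {}
    on_stack: set[int] = set()
    stack: list[int] = []
    counter = 0
    components: list[tuple[int, list[int]]] = []  # (root discovery index, nodes)

    for start in sorted(adj):
        if start in index:
            continue
        # Work stack holds (node, position in its successor list).
        work: list[tuple[int, int]] = [(start, 0)]
        while work:
            v, child_idx = work[-1]
            if child_idx == 0:
                index[v] = lowlink[v] = counter
                counter += 1
                stack.append(v)
                on_stack.add(v)
            advanced = False
            successors = adj[v]
            while child_idx < len(successors):
                w = successors[child_idx]
                child_idx += 1
                if w not in index:
                    work[-1] = (v, child_idx)
                    work.append((w, 0))
                    advanced = True
                    break
                if w in on_stack:
                    lowlink[v] = min(lowlink[v], index[w])
            if advanced:
                continue
            work.pop()
            if lowlink[v] == index[v]:  # v is the root of an SCC
                nodes = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    nodes.append(w)
                    if w == v:
                        break
                components.append((index[v], nodes))
            if work:
                parent, _ = work[-1]
                lowlink[parent] = min(lowlink[parent], lowlink[v])

    components.sort(key=lambda item: item[0])
    return _clusters_from_partition([nodes for _, nodes in components], graph)


def components_oracle(graph: AlignmentGraph) -> list[Cluster]:
    """Independent flood-fill component finder (test oracle only)."""
    adj = graph.adjacency()
    seen: set[int] = set()
    partition: list[list[int]] = []
    for start in sorted(adj):
        if start in seen:
            continue
        frontier = [start]
        seen.add(start)
        nodes = []
        while frontier:
            v = frontier.pop()
            nodes.append(v)
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    frontier.append(w)
        partition.append(nodes)
    return _clusters_from_partition(partition, graph)


def iccf(
    graph: AlignmentGraph,
    score_fn: Callable[[list[Cluster], AlignmentGraph], list],
    filter_rule: str = "go_coherence_nonzero",
    threshold: float = 0.5,
    max_iter: int = 10,
) -> ICCFResult:
    """Iterative connected-components finding.

    Alternates component detection, cluster scoring, and whole-cluster
    removal until a pass removes nothing (convergence) or ``max_iter`` is
    reached.  ``score_fn(clusters, subgraph)`` must return one score object
    per cluster exposing ``F`` (functional coherence) and ``score``.

    Rules: ``go_coherence_nonzero`` keeps clusters whose functional
    coherence F is non-zero; ``score_threshold`` keeps clusters whose
    combined score is at least ``threshold``.  Because scoring re-normalizes
    over surviving clusters each pass, the score-threshold rule can couple
    clusters and may need more than two passes; the coherence rule is
    cluster-local and settles in at most two.
    """
    if filter_rule not in ("go_coherence_nonzero", "score_threshold"):
        raise ValueError(f"unknown filter rule {filter_rule!r}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    surviving = set(graph.node_ids())
    removed_per_iteration: list[int] = []
    iterations = 0
    converged = False
    clusters: list[Cluster] = []
    while iterations < max_iter:
        iterations += 1
        subgraph = graph.subgraph(surviving)
        clusters = connected_components(subgraph)
        scores = score_fn(clusters, subgraph)
        if len(scores) != len(clusters):
            raise ValueError("score_fn returned a mismatched number of scores")
        if filter_rule == "go_coherence_nonzero":
            failed = [c for c, s in zip(clusters, scores) if not s.F > 0.0]
        else:
            failed = [
                c for c, s in zip(clusters, scores)
                if s.score is None or s.score < threshold
            ]
        removed_per_iteration.append(len(failed))
        if not failed:
            converged = True
            break
        for cluster in failed:
            surviving -= cluster.node_ids
    if not converged:
        clusters = connected_components(graph.subgraph(surviving))
    return ICCFResult(
        clusters=clusters,
        iterations=iterations,
        removed_per_iteration=removed_per_iteration,
        converged=converged,
    )


def filter_by_size(clusters: Iterable[Cluster], min_size: int = 2) -> list[Cluster]:
    """Reported clusters default to size >= 2 (singletons carry no
    conserved interaction)."""
    return [c for c in clusters if c.size >= min_size]
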