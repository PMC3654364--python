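"""Cross-species alignment-graph construction.

A node of the alignment graph is a tuple of proteins, exactly one per
aligned species, drawn from one homolog group.  An edge marks a conserved
interaction: for two species both within-species protein pairs must interact
directly; for three species at least ``min_direct`` species must interact
directly and every remaining species must connect the two proteins within a
bounded unweighted shortest-path distance (default 2).
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .io_formats import (
    HomologGroupTable,
    PPINetwork,
    SimilarityTable,
)

logger = logging.getLogger(__name__)

#: Cross-product enumeration cap per homolog group (promiscuous groups can
#: otherwise blow up combinatorially); configurable in build_nodes.
DEFAULT_GROUP_NODE_CAP = 64


@dataclass
class AlignmentNode:
    node_id: int
    members: dict[str, str]  # species id -> protein id (exactly one each)
    group_id: str

    def proteins(self) -> tuple[str, ...]:
        return tuple(self.members[sp] for sp in sorted(self.members))


@dataclass
class AlignmentGraph:
    nodes: list[AlignmentNode] = field(default_factory=list)
    edges: set[tuple[int, int]] = field(default_factory=set)
    #: per-edge, per-species support: "direct" or "distance-<d>"
    provenance: dict[tuple[int, int], dict[str, str]] = field(default_factory=dict)
    _by_id: Optional[dict[int, AlignmentNode]] = field(
        default=None, repr=False, compare=False
    )

    def node_by_id(self, node_id: int) -> AlignmentNode:
        if self._by_id is None or len(self._by_id) != len(self.nodes):
            self._by_id = {n.node_id: n for n in self.nodes}
        return self._by_id[node_id]

    def node_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes]

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {n.node_id: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def add_edge(self, u: int, v: int, provenance: dict[str, str]) -> None:
        if u == v:
            raise ValueError("self-edges are not allowed in the alignment graph")
        edge = (u, v) if u < v else (v, u)
        self.edges.add(edge)
        self.provenance[edge] = provenance

    def subgraph(self, node_ids) -> "AlignmentGraph":
        """Induced subgraph on a node-id subset (nodes shared, not copied)."""
        keep = set(node_ids)
        nodes = [n for n in self.nodes if n.node_id in keep]
        edges = {e for e in self.edges if e[0] in keep and e[1] in keep}
        provenance = {e: self.provenance[e] for e in edges if e in self.provenance}
        return AlignmentGraph(nodes=nodes, edges=edges, provenance=provenance)

    def validate(self) -> None:
        ids = set(self.node_ids())
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge on node {u}")
            if u not in ids or v not in ids:
                raise ValueError(f"edge ({u}, {v}) references a missing node")
            if (u, v) not in self.provenance:
                raise ValueError(f"edge ({u}, {v}) lacks provenance")


def interaction_universe(n: int) -> int:
    """Number of unordered protein pairs among ``n`` proteins: n(n-1)/2.

    This is the count of pairwise interaction tests needed to cover one
    species exhaustively (5000 proteins -> 12,497,500 tests), the
    combinatorial burden that motivates starting from precompiled homolog
    groups instead.
    """
    if n < 0:
        raise ValueError(f"protein count must be non-negative, got {n}")
    return n * (n - 1) // 2


# ---------------------------------------------------------------------------
# Node construction
# ---------------------------------------------------------------------------


def _combo_similarity_key(
    combo: tuple[str, ...], species: list[str], similarity: SimilarityTable
) -> tuple[float, tuple[str, ...]]:
    """Ranking key for best_pairs: sum of log10 e-values over species pairs
    (absent records rank worst), ties broken by the protein tuple."""
    total = 0.0
    for i, j in itertools.combinations(range(len(species)), 2):
        e_value = similarity.e_value(combo[i], combo[j])
        if e_value is None:
            return (math.inf, combo)
        total += math.log10(e_value)
    return (total, combo)


def build_nodes(
    homologs: HomologGroupTable,
    networks: list[PPINetwork],
    mode: str = "group_all_pairs",
    similarity: Optional[SimilarityTable] = None,
    group_node_cap: int = DEFAULT_GROUP_NODE_CAP,
) -> list[AlignmentNode]:
    """Enumerate alignment nodes from homolog groups.

    ``group_all_pairs`` emits the full cross-product of each group's
    per-species member lists (capped at ``group_node_cap`` nodes per group);
    ``best_pairs`` emits a single node per group, the member combination
    with the smallest cross-species e-values.  Only proteins present in the
    corresponding PPI network are eligible; groups not covering every
    aligned species are skipped.
    """
    if mode not in ("group_all_pairs", "best_pairs"):
        raise ValueError(f"unknown node mode {mode!r}")
    if mode == "best_pairs" and similarity is None:
        raise ValueError("best_pairs mode requires a similarity table")

    species = [net.species_id for net in networks]
    present = {net.species_id: net.proteins for net in networks}
    nodes: list[AlignmentNode] = []
    skipped = 0
    for group_id, per_species in homologs.groups.items():
        members = []
        complete = True
        for sp in species:
            eligible = [p for p in per_species.get(sp, []) if p in present[sp]]
            if not eligible:
                complete = False
                break
            members.append(eligible)
        if not complete:
            skipped += 1
            continue
        combos = itertools.product(*members)
        if mode == "best_pairs":
            best = min(
                combos, key=lambda c: _combo_similarity_key(c, species, similarity)
            )
            chosen = [best]
        else:
            chosen = []
            for combo in combos:
                if len(chosen) >= group_node_cap:
                    logger.warning(
                        "group %s: cross-product capped at %d nodes",
                        group_id, group_node_cap,
                    )
                    break
                chosen.append(combo)
        for combo in chosen:
            nodes.append(
                AlignmentNode(
                    node_id=len(nodes),
                    members=dict(zip(species, combo)),
                    group_id=group_id,
                )
            )
    if skipped:
        logger.info(
            "%d group(s) skipped: no alignable member in some species", skipped
        )
    return nodes


# ---------------------------------------------------------------------------
# Edge construction
# ---------------------------------------------------------------------------


def _check_nodes_in_networks(
    nodes: list[AlignmentNode], networks: list[PPINetwork]
) -> None:
    present = {net.species_id: net.proteins for net in networks}
    for node in nodes:
        for sp, protein in node.members.items():
            if protein not in present.get(sp, set()):
                raise ValueError(
                    f"node {node.node_id}: protein {protein!r} absent from "
                    f"network {sp!r}"
                )


def _shares_protein(u: AlignmentNode, v: AlignmentNode) -> bool:
    return any(u.members[sp] == v.members[sp] for sp in u.members)


def _direct_candidate_pairs(
    nodes: list[AlignmentNode], network: PPINetwork
) -> set[tuple[int, int]]:
    """Node pairs whose members in this species interact directly."""
    by_protein: dict[str, list[int]] = defaultdict(list)
    for node in nodes:
        by_protein[node.members[network.species_id]].append(node.node_id)
    pairs: set[tuple[int, int]] = set()
    for a, b in network.edges:
        for u in by_protein.get(a, ()):
            for v in by_protein.get(b, ()):
                if u != v:
                    pairs.add((u, v) if u < v else (v, u))
    return pairs


def _bounded_distance(
    adj: dict[str, set[str]], source: str, target: str, max_distance: int
) -> Optional[int]:
    """Unweighted shortest-path distance if <= max_distance, else None."""
    if source == target:
        return 0
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        protein, dist = frontier.popleft()
        if dist >= max_distance:
            continue
        for nxt in adj.get(protein, ()):
            if nxt == target:
                return dist + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, dist + 1))
    return None


def add_edges_pairwise(
    nodes: list[AlignmentNode], networks: list[PPINetwork]
) -> AlignmentGraph:
    """Conserved-interaction edges for a two-species alignment.

    An edge joins nodes u and v iff they share no protein and, in each
    species, u's member interacts directly with v's member.
    """
    if len(networks) != 2:
        raise ValueError(f"pairwise mode needs exactly 2 networks, got {len(networks)}")
    _check_nodes_in_networks(nodes, networks)
    graph = AlignmentGraph(nodes=list(nodes))
    first, second = networks
    candidates = _direct_candidate_pairs(nodes, first)
    for u, v in candidates:
        node_u, node_v = graph.node_by_id(u), graph.node_by_id(v)
        if _shares_protein(node_u, node_v):
            continue
        if second.has_edge(
            node_u.members[second.species_id], node_v.members[second.species_id]
        ):
            graph.add_edge(
                u, v,
                {first.species_id: "direct", second.species_id: "direct"},
            )
    graph.validate()
    return graph


def add_edges_multiway(
    nodes: list[AlignmentNode],
    networks: list[PPINetwork],
    min_direct: int = 2,
    max_indirect_distance: int = 2,
) -> AlignmentGraph:
    """Conserved-interaction edges for a three-species alignment.

    An edge joins u and v iff at least ``min_direct`` species have a direct
    interaction between u's and v's members, and every remaining species
    connects them within ``max_indirect_distance`` hops in its own network.
    Unreachable pairs simply yield no edge.
    """
    if len(networks) != 3:
        raise ValueError(f"multiway mode needs exactly 3 networks, got {len(networks)}")
    if not 1 <= min_direct <= 3:
        raise ValueError(f"min_direct must be in [1, 3], got {min_direct}")
    _check_nodes_in_networks(nodes, networks)
    graph = AlignmentGraph(nodes=list(nodes))
    # Any qualifying edge is direct in >=1 species, so the union of direct
    # candidate pairs over species covers all possible edges.
    candidates: set[tuple[int, int]] = set()
    for network in networks:
        candidates |= _direct_candidate_pairs(nodes, network)
    adjacencies = {net.species_id: net.adjacency() for net in networks}
    for u, v in sorted(candidates):
        node_u, node_v = graph.node_by_id(u), graph.node_by_id(v)
        if _shares_protein(node_u, node_v):
            continue
        provenance: dict[str, str] = {}
        n_direct = 0
        indirect_ok = True
        for network in networks:
            sp = network.species_id
            a, b = node_u.members[sp], node_v.members[sp]
            if network.has_edge(a, b):
                provenance[sp] = "direct"
                n_direct += 1
            else:
                dist = _bounded_distance(adjacencies[sp], a, b, max_indirect_distance)
                if dist is None:
                    indirect_ok = False
                    break
                provenance[sp] = f"distance-{dist}"
        if indirect_ok and n_direct >= min_direct:
            graph.add_edge(u, v, provenance)
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_alignment_graph(graph: AlignmentGraph, node_path, edge_path) -> None:
    """TSV export: node table and edge table with per-species provenance."""
    with open(node_path, "w", encoding="utf-8") as handle:
        handle.write("node_id\tgroup_id\tmembers\n")
        for node in sorted(graph.nodes, key=lambda n: n.node_id):
            members = ";".join(
                f"{sp}:{prot}" for sp, prot in sorted(node.members.items())
            )
            handle.write(f"{node.node_id}\t{node.group_id}\t{members}\n")
    with open(edge_path, "w", encoding="utf-8") as handle:
        handle.write("u\tv\tprovenance\n")
        for u, v in sorted(graph.edges):
            prov = ";".join(
                f"{sp}:{tag}" for sp, tag in sorted(graph.provenance[(u, v)].items())
            )
            handle.write(f"{u}\t{v}\t{prov}\n")


def read_alignment_graph(node_path, edge_path) -> AlignmentGraph:
    """Re-read the TSV export written by :func:`write_alignment_graph`."""
    graph = AlignmentGraph()
    with open(node_path, encoding="utf-8") as handle:
        handle.readline()
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            node_id, group_id, members_raw = line.split("\t")
            members = {}
            for item in members_raw.split(";"):
                sp, _, prot = item.partition(":")
                members[sp] = prot
            graph.nodes.append(
                AlignmentNode(node_id=int(node_id), members=members, group_id=group_id)
            )
    with open(edge_path, encoding="utf-8") as handle:
        handle.readline()
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            u, v, prov_raw = line.split("\t")
            provenance = {}
            for item in prov_raw.split(";"):
                sp, _, tag = item.partition(":")
                provenance[sp] = tag
            graph.add_edge(int(u), int(v), provenance)
    graph.validate()
    return graph


def to_networkx(graph: AlignmentGraph) -> nx.Graph:
    """Mirror as a networkx graph (e.g. for GraphML export)."""
    out = nx.Graph()
    for node in graph.nodes:
        attrs = {f"member_{sp}": prot for sp, prot in node.members.items()}
        out.add_node(node.node_id, group_id=node.group_id, **attrs)
    for (u, v) in graph.edges:
        attrs = {
            f"support_{sp}": tag for sp, tag in graph.provenance[(u, v)].items()
        }
        out.add_edge(u, v, **attrs)
    return out


def write_graphml(graph: AlignmentGraph, path) -> None:
    nx.write_graphml(to_networkx(graph), path)
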