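"""Readers and writers for the tab-separated dialects the aligner consumes.

Every external file is plain UTF-8 TSV; lines starting with ``#`` are
comments.  Protein identifiers are opaque strings, namespaced only by the
species they were loaded under — no identifier mapping is attempted, so the
caller is responsible for using a consistent naming scheme per species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

#: E-values of exactly zero (BLAST underflow) are floored here so that
#: ratios of e-values stay finite.
E_VALUE_FLOOR = 1e-180


class Namespace(str, Enum):
    """Annotation namespaces understood by the scoring and evaluation steps."""

    GO_BP = "GO_BP"
    KO = "KO"
    MIPS_COMPLEX = "MIPS_COMPLEX"
    MIPS_FUNCAT = "MIPS_FUNCAT"


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Unordered protein pair stored as a sorted tuple."""
    return (a, b) if a <= b else (b, a)


def _iter_rows(path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping blanks and comments."""
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """One species' undirected protein-protein interaction graph.

    Edges are canonical (sorted, deduplicated) tuples.  Self-interactions are
    recorded separately in :attr:`self_loops` and never appear in
    :attr:`edges`; the alignment-graph builder ignores them.
    """

    species_id: str
    proteins: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    self_loops: set[str] = field(default_factory=set)
    _adj: Optional[dict[str, set[str]]] = field(
        default=None, repr=False, compare=False
    )

    def add_edge(self, a: str, b: str, weight: Optional[float] = None) -> None:
        self.proteins.add(a)
        self.proteins.add(b)
        if a == b:
            self.self_loops.add(a)
            return
        edge = canonical_edge(a, b)
        self.edges.add(edge)
        if weight is not None:
            self.weights[edge] = weight
        self._adj = None

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def adjacency(self) -> dict[str, set[str]]:
        """Neighbour sets, cached; rebuilt after any mutation."""
        if self._adj is None:
            adj: dict[str, set[str]] = {p: set() for p in self.proteins}
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            self._adj = adj
        return self._adj

    def validate(self) -> None:
        for a, b in self.edges:
            if a not in self.proteins or b not in self.proteins:
                raise ValueError(
                    f"edge ({a}, {b}) references a protein absent from "
                    f"network {self.species_id!r}"
                )
            if a == b:
                raise ValueError(f"self-loop ({a}, {b}) stored as an edge")


@dataclass
class HomologGroupTable:
    """Cross-species ortholog/homolog group membership (KO-style).

    ``groups`` maps group id -> species id -> member proteins in file order.
    A protein may belong to several groups; membership lookup returns a set.
    """

    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, group_id: str, species_id: str, protein_id: str) -> bool:
        """Add one membership row; returns False for an exact duplicate."""
        species = self.groups.setdefault(group_id, {})
        members = species.setdefault(species_id, [])
        if protein_id in members:
            return False
        members.append(protein_id)
        return True

    def membership(self, protein_id: str) -> set[str]:
        """All group ids containing the protein (under any species)."""
        return {
            gid
            for gid, species in self.groups.items()
            for members in species.values()
            if protein_id in members
        }

    def species_members(self, group_id: str, species_id: str) -> list[str]:
        return list(self.groups.get(group_id, {}).get(species_id, []))


@dataclass
class SimilarityTable:
    """Best BLAST hit per ordered protein pair: (e-value, bit score)."""

    records: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )

    def add(self, query: str, subject: str, e_value: float, bit_score: float) -> None:
        if e_value <= 0.0:
            e_value = E_VALUE_FLOOR
        key = (query, subject)
        current = self.records.get(key)
        if current is None or e_value < current[0]:
            self.records[key] = (e_value, bit_score)

    def e_value(self, a: str, b: str) -> Optional[float]:
        """Smallest e-value over both hit directions; None when absent.

        Absence is a distinct outcome, deliberately not conflated with 0.
        """
        best = None
        for key in ((a, b), (b, a)):
            rec = self.records.get(key)
            if rec is not None and (best is None or rec[0] < best):
                best = rec[0]
        return best


@dataclass
class AnnotationMap:
    """Protein -> term-id sets within one fixed namespace."""

    namespace: Namespace
    terms: dict[str, set[str]] = field(default_factory=dict)

    def terms_for(self, protein_id: str) -> set[str]:
        return self.terms.get(protein_id, set())

    def add(self, protein_id: str, term_id: str) -> None:
        self.terms.setdefault(protein_id, set()).add(term_id)

    def annotated_proteins(self) -> set[str]:
        return {p for p, t in self.terms.items() if t}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_ppi_network(
    path,
    species_id: str,
    dialect: str = "tsv2col",
    weight_cutoff: Optional[float] = None,
) -> PPINetwork:
    """Read a per-species PPI edge list.

    Parameters
    ----------
    dialect
        ``tsv2col`` (protein, protein) or ``tsv3col_weighted`` (protein,
        protein, weight in [0, 1]).
    weight_cutoff
        For the weighted dialect, drop edges whose interaction probability
        is at or below this value (the tool's default cutoff is 0.5).
    """
    if dialect not in ("tsv2col", "tsv3col_weighted"):
        raise ValueError(f"unknown PPI dialect {dialect!r}")
    expected = 2 if dialect == "tsv2col" else 3
    network = PPINetwork(species_id=species_id)
    for lineno, fields in _iter_rows(path):
        if len(fields) != expected:
            raise ParseError(
                path, lineno,
                f"expected {expected} tab-separated fields, got {len(fields)}",
            )
        a, b = fields[0], fields[1]
        if not a or not b:
            raise ParseError(path, lineno, "empty protein identifier")
        weight = None
        if expected == 3:
            try:
                weight = float(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric weight {fields[2]!r}")
            if not 0.0 <= weight <= 1.0:
                raise ParseError(path, lineno, f"weight {weight} outside [0, 1]")
            if weight_cutoff is not None and weight <= weight_cutoff:
                # Protein identities are still recorded so the node builder
                # can tell "absent" from "filtered".
                network.proteins.update((a, b))
                continue
        network.add_edge(a, b, weight)
    if network.self_loops:
        logger.warning(
            "%s: %d self-interaction(s) recorded and excluded from the edge set",
            path, len(network.self_loops),
        )
    network.validate()
    return network


def read_homolog_groups(path) -> HomologGroupTable:
    """Read a 3-column TSV: group-id, species-id, protein-id."""
    table = HomologGroupTable()
    duplicates = 0
    for lineno, fields in _iter_rows(path):
        if len(fields) != 3:
            raise ParseError(
                path, lineno, f"expected 3 tab-separated fields, got {len(fields)}"
            )
        group_id, species_id, protein_id = fields
        if not (group_id and species_id and protein_id):
            raise ParseError(path, lineno, "empty field")
        if not table.add(group_id, species_id, protein_id):
            duplicates += 1
    if duplicates:
        logger.warning("%s: %d duplicate membership row(s) collapsed", path, duplicates)
    return table


def read_blast_tabular(path) -> SimilarityTable:
    """Read BLAST tabular output (outfmt 6, or a 4-column subset).

    Full outfmt-6 rows use columns 11/12 for e-value and bit score; a
    minimal dialect of exactly (query, subject, e-value, bit-score) is also
    accepted.  The best (smallest-e) record is kept per ordered pair, and
    e-values of 0 are floored at ``E_VALUE_FLOOR``.
    """
    table = SimilarityTable()
    for lineno, fields in _iter_rows(path):
        if len(fields) >= 12:
            query, subject, e_raw, bits_raw = fields[0], fields[1], fields[10], fields[11]
        elif len(fields) == 4:
            query, subject, e_raw, bits_raw = fields
        else:
            raise ParseError(
                path, lineno,
                f"expected 4 or >=12 tab-separated fields, got {len(fields)}",
            )
        try:
            e_value = float(e_raw)
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric e-value {e_raw!r}")
        try:
            bit_score = float(bits_raw)
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric bit score {bits_raw!r}")
        if e_value < 0:
            raise ParseError(path, lineno, f"negative e-value {e_value}")
        table.add(query, subject, e_value, bit_score)
    return table


#: GAF 2.x column positions (0-based) for the fields we use.
_GAF_OBJECT_ID = 1
_GAF_TERM_ID = 4
_GAF_ASPECT = 8


def read_annotations(path, namespace: Namespace, dialect: str = "tsv2") -> AnnotationMap:
    """Read protein -> term annotations.

    ``tsv2`` is a plain two-column TSV (protein-id, term-id).  ``gaf``
    accepts GAF 2.x rows (``!`` comment lines skipped); when the namespace
    is GO biological process only aspect-P rows are retained.
    """
    namespace = Namespace(namespace)
    annotation = AnnotationMap(namespace=namespace)
    if dialect == "tsv2":
        for lineno, fields in _iter_rows(path):
            if len(fields) != 2:
                raise ParseError(
                    path, lineno, f"expected 2 tab-separated fields, got {len(fields)}"
                )
            protein_id, term_id = fields
            if not protein_id or not term_id:
                raise ParseError(path, lineno, "empty field")
            annotation.add(protein_id, term_id)
    elif dialect == "gaf":
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) <= _GAF_ASPECT:
                    raise ParseError(
                        path, lineno, f"GAF row with only {len(fields)} columns"
                    )
                if namespace is Namespace.GO_BP and fields[_GAF_ASPECT] != "P":
                    continue
                annotation.add(fields[_GAF_OBJECT_ID], fields[_GAF_TERM_ID])
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return annotation


# ---------------------------------------------------------------------------
# Cluster report
# ---------------------------------------------------------------------------

_CLUSTER_HEADER = [
    "cluster_id", "size", "members",
    "S", "I_raw", "I_norm", "F", "Score", "p_S", "p_I", "p_F",
]


def _format_members(cluster, graph) -> str:
    """Node tuples as ``species:protein`` joined by ``,`` within a node and
    ``;`` between nodes, in ascending node-id order."""
    parts = []
    for node_id in sorted(cluster.node_ids):
        node = graph.node_by_id(node_id)
        parts.append(
            ",".join(f"{sp}:{prot}" for sp, prot in sorted(node.members.items()))
        )
    return ";".join(parts)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    return f"{value:.6g}"


def write_clusters(clusters, scores, path, graph=None, significance=None) -> None:
    """Write the cluster report TSV.

    Rows are ordered by descending combined score (unscored clusters last),
    ties broken by cluster id, so output is deterministic.  ``scores`` and
    ``significance`` may be None (columns written as NA).
    """
    if scores is not None and len(scores) != len(clusters):
        raise ValueError(
            f"{len(clusters)} clusters but {len(scores)} scores"
        )
    if significance is not None and len(significance) != len(clusters):
        raise ValueError(
            f"{len(clusters)} clusters but {len(significance)} significance results"
        )

    def sort_key(idx: int):
        score = scores[idx].score if scores is not None else None
        return (-(score if score is not None else float("-inf")),
                clusters[idx].cluster_id)

    order = sorted(range(len(clusters)), key=sort_key)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(_CLUSTER_HEADER) + "\n")
        for idx in order:
            cluster = clusters[idx]
            if graph is not None:
                members = _format_members(cluster, graph)
            else:
                members = ";".join(str(n) for n in sorted(cluster.node_ids))
            sc = scores[idx] if scores is not None else None
            sig = significance[idx] if significance is not None else None
            row = [
                str(cluster.cluster_id),
                str(cluster.size),
                members,
                _fmt(sc.S if sc else None),
                _fmt(sc.I_raw if sc else None),
                _fmt(sc.I_norm if sc else None),
                _fmt(sc.F if sc else None),
                _fmt(sc.score if sc else None),
                _fmt(sig.p_S if sig else None),
                _fmt(sig.p_I if sig else None),
                _fmt(sig.p_F if sig else None),
            ]
            handle.write("\t".join(row) + "\n")


def read_clusters(path) -> list[dict]:
    """Re-read a cluster report; returns one dict per row.

    ``members`` is a list of nodes, each a sorted list of (species, protein)
    pairs; numeric columns come back as floats or None for NA.
    """
    rows = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _CLUSTER_HEADER:
            raise ParseError(path, 1, f"unexpected header {header!r}")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_CLUSTER_HEADER):
                raise ParseError(
                    path, lineno, f"expected {len(_CLUSTER_HEADER)} fields"
                )
            members = []
            if fields[2]:
                for node_part in fields[2].split(";"):
                    pairs = []
                    for item in node_part.split(","):
                        species, _, protein = item.partition(":")
                        pairs.append((species, protein))
                    members.append(pairs)
            numeric = {
                name: (None if raw == "NA" else float(raw))
                for name, raw in zip(_CLUSTER_HEADER[3:], fields[3:])
            }
            rows.append(
                {
                    "cluster_id": int(fields[0]),
                    "size": int(fields[1]),
                    "members": members,
                    **numeric,
                }
            )
    return rows
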