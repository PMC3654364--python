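"""Synthetic cross-species benchmarks with planted conserved modules.

The generator emulates the structure the aligner assumes in real data: a
set of 1:1 orthologous groups whose proteins form conserved interacting
modules (cliques or paths) mirrored across species, embedded in sparse
random background networks, with BLAST-like e-values separating orthologs
from decoys and with module-coherent GO/KO/MIPS annotations.  Ground truth
(which groups form which module, which term was planted) is returned
alongside, so recovery can be measured exactly.

Everything is driven by one integer seed; the same seed reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    AnnotationMap,
    HomologGroupTable,
    Namespace,
    PPINetwork,
    SimilarityTable,
    canonical_edge,
)

SPECIES_POOL = ("spA", "spB", "spC")
#: log10 e-value ranges: orthologs well below the close-homologue regime
#: (much smaller than e^-7), decoys clearly outside it.
ORTHOLOG_LOG10_E = (-40.0, -20.0)
DECOY_LOG10_E = (-3.0, 0.0)
N_BACKGROUND_GO_TERMS = 20
N_BACKGROUND_MIPS_TERMS = 10


@dataclass
class BenchmarkConfig:
    """Study conditions for one synthetic benchmark.

    Defaults describe a small two-species alignment problem: 200 proteins
    per species, five conserved 4-protein clique modules, sparse background
    (edge probability 0.005, about the density of curated PPI networks at
    this size), 10% conserved-edge dropout, ten decoy ortholog groups and
    5% annotation noise.
    """

    n_species: int = 2
    n_proteins: int = 200
    n_modules: int = 5
    module_size: int = 4
    module_topology: str = "clique"
    background_edge_prob: float = 0.005
    conserved_edge_dropout: float = 0.1
    n_decoy_groups: int = 10
    annotation_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_species not in (2, 3):
            raise ValueError(f"n_species must be 2 or 3, got {self.n_species}")
        if self.module_topology not in ("clique", "path"):
            raise ValueError(f"unknown topology {self.module_topology!r}")
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError(
                f"{self.n_modules} modules of size {self.module_size} do not "
                f"fit in {self.n_proteins} proteins"
            )
        for name in ("background_edge_prob", "conserved_edge_dropout", "annotation_noise"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.n_decoy_groups < 0 or self.module_size < 1 or self.n_modules < 0:
            raise ValueError("counts must be non-negative (module_size >= 1)")


@dataclass
class GroundTruth:
    """What was planted: module -> group ids, group -> per-species protein,
    module -> planted GO term."""

    planted_modules: list[set[str]]
    ortholog_map: dict[str, dict[str, str]]
    planted_terms: dict[int, str]

    def group_to_module(self) -> dict[str, int]:
        return {
            gid: idx
            for idx, groups in enumerate(self.planted_modules)
            for gid in groups
        }


@dataclass
class Benchmark:
    config: BenchmarkConfig
    networks: list[PPINetwork]
    homologs: HomologGroupTable
    similarity: SimilarityTable
    annotations: dict[Namespace, AnnotationMap]
    truth: GroundTruth


@dataclass
class RecoveryResult:
    module_recall: float
    node_precision: float
    node_precision_defined: bool


def _protein(species: str, index: int) -> str:
    return f"{species}_p{index:04d}"


def _module_edges(indices: list[int], topology: str) -> list[tuple[int, int]]:
    if topology == "clique":
        return [
            (indices[i], indices[j])
            for i in range(len(indices))
            for j in range(i + 1, len(indices))
        ]
    return [(indices[i], indices[i + 1]) for i in range(len(indices) - 1)]


def generate_benchmark(config: BenchmarkConfig) -> Benchmark:
    """Generate networks, homolog table, similarity, annotations and truth."""
    rng = np.random.default_rng(config.seed)
    species = list(SPECIES_POOL[: config.n_species])
    n = config.n_proteins

    # --- planted modules: protein index k is orthologous across species ---
    planted_modules: list[set[str]] = []
    ortholog_map: dict[str, dict[str, str]] = {}
    planted_terms: dict[int, str] = {}
    homologs = HomologGroupTable()
    module_indices: list[list[int]] = []
    for m in range(config.n_modules):
        indices = list(range(m * config.module_size, (m + 1) * config.module_size))
        module_indices.append(indices)
        groups = set()
        for j, idx in enumerate(indices):
            gid = f"G{m:02d}_{j}"
            groups.add(gid)
            ortholog_map[gid] = {sp: _protein(sp, idx) for sp in species}
            for sp in species:
                homologs.add(gid, sp, _protein(sp, idx))
        planted_modules.append(groups)
        planted_terms[m] = f"GO:M{m:03d}"

    n_module_proteins = config.n_modules * config.module_size
    free_indices = np.arange(n_module_proteins, n)

    # --- decoy groups over random non-module proteins ---
    decoy_ids = []
    if config.n_decoy_groups:
        if len(free_indices) < config.n_decoy_groups:
            raise ValueError("not enough non-module proteins for the decoy groups")
        decoy_choice = {
            sp: rng.choice(free_indices, size=config.n_decoy_groups, replace=False)
            for sp in species
        }
        for d in range(config.n_decoy_groups):
            gid = f"D{d:02d}"
            decoy_ids.append(gid)
            ortholog_map[gid] = {
                sp: _protein(sp, int(decoy_choice[sp][d])) for sp in species
            }
            for sp in species:
                homologs.add(gid, sp, ortholog_map[gid][sp])

    # --- networks: planted edges with per-species dropout + ER background ---
    planted_pairs = [
        pair
        for indices in module_indices
        for pair in _module_edges(indices, config.module_topology)
    ]
    networks = []
    for sp in species:
        network = PPINetwork(species_id=sp)
        network.proteins = {_protein(sp, i) for i in range(n)}
        keep = rng.random(len(planted_pairs)) >= config.conserved_edge_dropout
        for (i, j), kept in zip(planted_pairs, keep):
            if kept:
                network.add_edge(_protein(sp, i), _protein(sp, j))
        if config.background_edge_prob > 0 and n > 1:
            rows, cols = np.triu_indices(n, k=1)
            mask = rng.random(len(rows)) < config.background_edge_prob
            planted_set = {canonical_edge(_protein(sp, i), _protein(sp, j))
                           for i, j in planted_pairs}
            for i, j in zip(rows[mask], cols[mask]):
                edge = canonical_edge(_protein(sp, int(i)), _protein(sp, int(j)))
                if edge not in planted_set:
                    network.add_edge(*edge)
        network.proteins = {_protein(sp, i) for i in range(n)}
        network.validate()
        networks.append(network)

    # --- similarity: orthologs strong, decoys weak ---
    similarity = SimilarityTable()
    for gid in sorted(ortholog_map):
        low, high = DECOY_LOG10_E if gid.startswith("D") else ORTHOLOG_LOG10_E
        members = ortholog_map[gid]
        for a_idx in range(len(species)):
            for b_idx in range(a_idx + 1, len(species)):
                e_value = float(10.0 ** rng.uniform(low, high))
                a = members[species[a_idx]]
                b = members[species[b_idx]]
                similarity.add(a, b, e_value, bit_score=round(-10.0 * math.log10(e_value), 1))

    # --- annotations ---
    go = AnnotationMap(namespace=Namespace.GO_BP)
    ko = AnnotationMap(namespace=Namespace.KO)
    mips_cpx = AnnotationMap(namespace=Namespace.MIPS_COMPLEX)
    mips_fc = AnnotationMap(namespace=Namespace.MIPS_FUNCAT)
    go_pool = [f"GO:B{i:03d}" for i in range(N_BACKGROUND_GO_TERMS)]
    cpx_pool = [f"CPX:B{i:02d}" for i in range(N_BACKGROUND_MIPS_TERMS)]
    fc_pool = [f"FC:B{i:02d}" for i in range(N_BACKGROUND_MIPS_TERMS)]

    def _noisy(term: str, pool: list[str]) -> str:
        if config.annotation_noise > 0 and rng.random() < config.annotation_noise:
            return pool[int(rng.integers(len(pool)))]
        return term

    for sp in species:
        for m, indices in enumerate(module_indices):
            for idx in indices:
                protein = _protein(sp, idx)
                go.add(protein, _noisy(planted_terms[m], go_pool))
                mips_cpx.add(protein, _noisy(f"CPX:M{m:03d}", cpx_pool))
                mips_fc.add(protein, _noisy(f"FC:M{m:03d}", fc_pool))
        for idx in range(n_module_proteins, n):
            protein = _protein(sp, idx)
            go.add(protein, go_pool[int(rng.integers(len(go_pool)))])
            mips_cpx.add(protein, cpx_pool[int(rng.integers(len(cpx_pool)))])
            mips_fc.add(protein, fc_pool[int(rng.integers(len(fc_pool)))])
    # KO terms mirror group membership (the KO table is the homolog table).
    ko_pool = sorted(ortholog_map)
    for gid in sorted(ortholog_map):
        for sp in species:
            ko.add(ortholog_map[gid][sp], _noisy(gid, ko_pool))

    truth = GroundTruth(
        planted_modules=planted_modules,
        ortholog_map=ortholog_map,
        planted_terms=planted_terms,
    )
    return Benchmark(
        config=config,
        networks=networks,
        homologs=homologs,
        similarity=similarity,
        annotations={
            Namespace.GO_BP: go,
            Namespace.KO: ko,
            Namespace.MIPS_COMPLEX: mips_cpx,
            Namespace.MIPS_FUNCAT: mips_fc,
        },
        truth=truth,
    )


def recovery_metrics(clusters, truth: GroundTruth, graph) -> RecoveryResult:
    """Module recall and node precision against the planted ground truth.

    A module is recovered when one cluster contains at least half (rounded
    up) of its groups; precision is the fraction of clustered nodes whose
    group was planted (not a decoy).
    """
    group_to_module = truth.group_to_module()
    n_modules = len(truth.planted_modules)
    recovered = set()
    clustered_nodes = 0
    planted_nodes = 0
    for cluster in clusters:
        groups_by_module: dict[int, set[str]] = {}
        for node_id in cluster.node_ids:
            node = graph.node_by_id(node_id)
            clustered_nodes += 1
            module = group_to_module.get(node.group_id)
            if module is not None:
                planted_nodes += 1
                groups_by_module.setdefault(module, set()).add(node.group_id)
        for module, groups in groups_by_module.items():
            need = math.ceil(len(truth.planted_modules[module]) / 2)
            if len(groups) >= need:
                recovered.add(module)
    recall = len(recovered) / n_modules if n_modules else 0.0
    if clustered_nodes == 0:
        return RecoveryResult(recall, 0.0, node_precision_defined=False)
    return RecoveryResult(
        recall, planted_nodes / clustered_nodes, node_precision_defined=True
    )


# ---------------------------------------------------------------------------
# File export (the `simulate` CLI subcommand)
# ---------------------------------------------------------------------------


def write_benchmark(benchmark: Benchmark, outdir) -> dict[str, str]:
    """Write all standard input files plus a ground-truth JSON; returns the
    path of each artifact keyed by role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for network in benchmark.networks:
        path = outdir / f"ppi_{network.species_id}.tsv"
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("# protein_a\tprotein_b\n")
            for a, b in sorted(network.edges):
                handle.write(f"{a}\t{b}\n")
        paths[f"ppi_{network.species_id}"] = str(path)
    path = outdir / "homologs.tsv"
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# group_id\tspecies_id\tprotein_id\n")
        for gid in sorted(benchmark.homologs.groups):
            for sp in sorted(benchmark.homologs.groups[gid]):
                for protein in benchmark.homologs.groups[gid][sp]:
                    handle.write(f"{gid}\t{sp}\t{protein}\n")
    paths["homologs"] = str(path)
    path = outdir / "blast.tsv"
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# query\tsubject\te_value\tbit_score\n")
        for (query, subject) in sorted(benchmark.similarity.records):
            e_value, bits = benchmark.similarity.records[(query, subject)]
            handle.write(f"{query}\t{subject}\t{e_value:.6e}\t{bits}\n")
    paths["blast"] = str(path)
    filenames = {
        Namespace.GO_BP: "go_bp.tsv",
        Namespace.KO: "ko.tsv",
        Namespace.MIPS_COMPLEX: "mips_complex.tsv",
        Namespace.MIPS_FUNCAT: "mips_funcat.tsv",
    }
    for namespace, annotation in benchmark.annotations.items():
        path = outdir / filenames[namespace]
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("# protein_id\tterm_id\n")
            for protein in sorted(annotation.terms):
                for term in sorted(annotation.terms[protein]):
                    handle.write(f"{protein}\t{term}\n")
        paths[namespace.value.lower()] = str(path)
    path = outdir / "ground_truth.json"
    truth = benchmark.truth
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(
            {
                "planted_modules": [sorted(g) for g in truth.planted_modules],
                "ortholog_map": truth.ortholog_map,
                "planted_terms": {str(k): v for k, v in truth.planted_terms.items()},
            },
            handle,
            indent=1,
            sort_keys=True,
        )
        handle.write("\n")
    paths["ground_truth"] = str(path)
    return paths
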