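# Methods

## Model and procedure

The aligner treats each species' interactome as an undirected graph and the
cross-species comparison as a graph-construction problem rather than a
search problem.  Homology is taken as given: a KO-style group table assigns
proteins to functional ortholog groups, and only proteins present in their
species' PPI network are considered alignable.  From each group covering
all aligned species, alignment nodes are enumerated either as the full
cross-product of per-species member lists (`group_all_pairs`) or as the
single member combination with the smallest cross-species BLAST e-values
(`best_pairs`, ties broken by lexicographic protein id).  The cross-product
is capped (default 64 nodes per group, logged) because promiscuous groups
grow multiplicatively and contribute little beyond noise.

Edges encode conserved interactions.  Pairwise, both within-species protein
pairs must interact directly.  Three-way, at least `min_direct = 2` species
must interact directly and each remaining species must connect the pair
within `max_indirect_distance = 2` unweighted hops; per-species support
(direct vs. distance-d) is kept as edge provenance.  Nodes sharing a
protein are never joined: a protein cannot conserve an interaction with
itself across one node pair.  Self-interactions in input networks are
recorded and flagged but ignored during edge building.

Conserved regions are the connected components of this graph.  The finder
is Tarjan's strongly-connected-components algorithm run on the symmetrized
arc set, where SCCs coincide with connected components; it uses an explicit
work stack (no recursion-depth limit) and visits nodes in ascending id, so
cluster ids are deterministic.  An independent flood-fill implementation
exists purely as a test oracle and the two are cross-checked on randomized
graphs; a doubling test asserts near-linear scaling in nodes + edges.

## Scoring

`Score(C) = w1·S + w2·I + w3·F` with default weights 1/3 each; every
component is in [0, 1].

* **S** averages per-node homology confidence.  BLAST mode: a node's
  e-value is its cross-species pair's best e-value (geometric mean over
  species pairs for three-way); with Ē the arithmetic mean over the
  cluster's nodes, confidence is 1 when the node's e-value ≤ Ē, else
  Ē / E.  Both "BLAST score" quantities are read as e-values (smaller =
  better); only that reading keeps the ratio in [0, 1].  Ortholog mode:
  confidence is 1 iff all of a node's members share a KO term, applied per
  node so the per-node s(k) stays meaningful; e-values of 0 are floored at
  1e-180 to keep ratios finite.  Missing similarity records give
  confidence 0 (logged), never an exception.
* **I** is i(C) / (|C|(|C|−1)/2) and is then normalized across the
  clusters of the batch: values above the mean become 1.0, the rest are
  divided by the mean.  Normalization is mandatory for I, optional (off by
  default) for S and F — S's confidence rules are already cluster-relative
  and F is already a bounded ratio.  Singleton clusters are not scorable
  for I; they carry I = 0 into the combined score and are excluded from
  the normalization mean.
* **F** is computed per species over the cluster's annotated member
  proteins as |∩ term sets| / |∪ term sets| and averaged over species.
  Unannotated proteins are excluded from numerator and denominator; a
  species needs ≥ 2 annotated members to contribute; F = 0 when every
  species is skipped.  No GO-DAG propagation is performed — term sets are
  taken as given, which makes F conservative for shallow annotations.

**Significance.**  For each cluster, N (default 3000, minimum 100) random
node subsets of the same size are drawn uniformly from the alignment graph
with a seeded generator, each component is recomputed on them, and
p = (R+1)/(N+1) with R the count of null values ≥ the observation.  Null
clusters are subsets, not connected subgraphs: connectivity is exactly what
the I statistic should detect, so conditioning the null on it would erase
the signal.  A significance-weighted sum of the three (R+1)/(N+1) terms is
reported alongside; note it runs opposite in direction to the combined
score (smaller = more significant), so ranking uses the combined score and
the p-values act as filters.

**ICCF.**  Component finding, scoring and whole-cluster removal alternate
until a pass removes nothing (or `max_iter = 10` is hit, flagged
non-converged).  The GO-coherence rule (drop clusters with F = 0) is
cluster-local, so it converges in at most two passes.  The score-threshold
rule re-normalizes I over survivors each pass, which couples clusters and
can need more passes; this is accepted rather than freezing the first-pass
normalization, because scores are defined relative to the reported set.
Removal is always whole-cluster; node-level pruning is out of scope.

## Evaluation

Equivalence classes are single alignment nodes; a node is correct when all
its members share a KO term.  Under this reading Ceq and Cnode coincide
identically (and when nodes are built from the same KO table used for
assessment, both are 1 by construction — this structural identity is an
acceptance check).  Tot counts homolog groups with every aligned species
represented in its PPI network; note that 2-column edge-list inputs define
a network by its interactions, so isolated proteins are not representable
in files and interaction-less groups do not count toward Tot in file-based
runs.  GO process coherence uses an in-package hypergeometric
upper-tail test with Benjamini–Hochberg FDR (α = 0.05 default) against the
species' full network as background; a cluster is coherent when any
biological-process term passes, specificity is the coherent fraction per
species, and sensitivity the number of distinct enriched terms.  MIPS
coverage marks a cluster covered only when all assessed members share a
complex (or FunCat) term.

## Synthetic benchmark

The generator plants `n_modules` modules of `module_size` 1:1-orthologous
groups whose within-species subgraph is a clique or path mirrored across
species; each conserved edge is deleted independently per species with
probability `conserved_edge_dropout`; background edges are Erdős–Rényi
with `background_edge_prob`; decoy groups link random non-module proteins.
Ortholog e-values are log-uniform in [1e-40, 1e-20] and decoys in
[1e-3, 1], so the close-homologue regime is cleanly separated.  Module
members share a planted GO term, a MIPS complex and FunCat term, and KO
terms mirror group membership; `annotation_noise` replaces planted terms
with random pool terms at the given rate.  Defaults (2 species × 200
proteins, five 4-clique modules, background 0.005, dropout 0.1, ten
decoys, noise 0.05, seed 0) describe a small but non-trivial problem:
sparse like curated PPI data at that scale, with enough noise that
recovery is good but not vacuously perfect.  What the generator does *not*
emulate: heavy-tailed degree distributions, correlated (non-independent)
edge loss between species, many-to-many ortholog groups with paralog
interference, and incomplete interactome coverage varying by species — so
perfect recovery here demonstrates correctness of the machinery, not
expected performance on real interactomes.  Tests that require exact
recovery switch dropout, background and noise to 0; the acceptance-style
checks otherwise run at stated sizes (e.g. 2×500 proteins, 25 modules) to
keep full runs under a few seconds.

Recovery metrics: a module counts as recalled when one cluster contains at
least half (rounded up) of its groups; node precision is the fraction of
clustered nodes originating from planted groups, with an explicit
"undefined" flag when nothing was clustered.

## Numerical and design choices

* Deterministic everywhere: node ids follow table order, traversal order is
  ascending id, report rows sort by descending score then cluster id, and
  all randomness flows through `numpy.random.default_rng(seed)`.
* Weights must sum to 1 within 1e-9; score identities are maintained to
  1e-12.
* Best-pairs ranking sums log10 e-values across species pairs to avoid
  underflow; absent similarity records rank worst rather than erroring.
* Normalization with an all-zero mean maps everything to 0 (logged) rather
  than dividing by zero.
* Minimum reported cluster size defaults to 2; singletons conserve nothing.
* The empirical p-value counts ties in R, keeping the estimator
  conservative (stochastically ≥ uniform under the null).

## Known limitations

At most three species; no overlapping clusters or seed-and-extend local
search; no ID mapping between naming schemes (inputs must use one scheme
per species); no GO-DAG ancestor closure; no automatic weight learning.
The I-normalization makes combined scores batch-relative, so scores are
comparable within one run, not across runs.
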