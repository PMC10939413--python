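# Methods

This note documents the models and procedures implemented in `gcnkit`,
the parameters that matter, and the design decisions taken where the
methodology left choices open.

## Normalization and filtering

Counts are normalized to FPKM once, from the raw count matrix, with
per-sample totals computed over all genes of the ingested matrix:
`FPKM(g,s) = counts(g,s)·10⁹ / (len_bp(g)·total(s))`. Grouped matrices
restrict the columns of this single global FPKM matrix; per-group totals
are **not** recomputed. Rationale: normalization describes sequencing
depth of a library, which does not change when the library is assigned to
a group.

The low-expression filter removes a gene when the number of libraries
with FPKM < `min_fpkm` (default 0.5) is **at least** `min_fraction`
(default 0.5) of the libraries. The boundary is inclusive — at exactly
50 % low-expression libraries a gene is removed — so survival requires
adequate expression in a strict majority. This choice is deterministic
and conservative; both knobs are configurable. Zero-variance genes are
removed at the same time because their Pearson correlation is undefined;
doing it here rather than erroring downstream keeps the failure local.
Filtering is idempotent.

Bioproject groups with fewer than `min_libraries = 6` libraries are
dropped before per-group filtering: correlation estimates from a handful
of libraries are too unstable to aggregate. Because each group is
filtered independently, a gene expressed only under one study's
conditions survives in that group even if it fails the global filter —
this is the mechanism by which aggregated networks cover more genes than
pooled ones.

## Network inference

**Ranks.** Pairwise Pearson correlation is computed on the filtered FPKM
values as given (no log transform). Each gene's partners are ranked by
descending correlation; equal correlations are ranked by lexicographic
gene id, which makes ranks reproducible across platforms and BLAS
builds. At least 3 samples are required.

**HRR.** `HRR(x,y) = max(rank(x,y), rank(y,x))` — low values mean both
genes place each other near the top of their partner lists. The network
at sparsity `k` is the undirected **union of each gene's k best partners
by ascending HRR** (ties by HRR, then gene id). Union semantics — rather
than keeping only edges with `HRR ≤ k` — is the variant whose minimum
degree equals `k` exactly while hub degrees can be several times `k`,
the topology signature of this network family. The strict variant
remains available via `strict_mutual=True` for comparison. Edge sets are
monotone in `k` (top-100 ⊆ top-300 from the same HRR matrix) and
invariant under sample permutation and global positive scaling of the
expression values (Pearson invariances).

**COO.** Per-group HRR networks (built at the same `k` as the final
network) are aggregated by edge co-occurrence frequency: the number of
group networks containing the edge. Each gene keeps its `k` best
partners by descending frequency. Frequencies are small integers, so
ties are common; they are broken by the lower mean HRR score of the edge
across the groups that contain it (the method's own strength score is
the natural secondary key), then lexicographically. The node universe is
the union of the group node sets, never the intersection.

## Evaluation: neighbor voting

For each term of an annotation collection (after intersecting term gene
sets with the network nodes and keeping sizes in [20, 1000]): member
genes are partitioned into `n_folds = 3` seeded folds. With one fold
hidden, every gene's vote is the fraction of its direct neighbors among
the training positives; edges vote as present/absent (HRR scores and COO
frequencies are not used as weights by default — no weighting rule is
part of the method's definition, and binary voting keeps the evaluator
identical across network types). Hidden positives are ranked among all
non-training genes and the ROC area is computed by the Mann–Whitney
rank-sum identity with mid-rank ties, which makes the rank-sum and
integrated-ROC definitions coincide exactly under ties; the term's AUROC
is the mean over folds. A three-fold default follows the convention of
the neighbor-voting literature; it is configurable. Genes annotated to a
term but absent from the network are excluded (unrankable); terms with
fewer member genes than folds are skipped with a warning.

Seeding: one integer seed drives everything. Per-term fold assignment
uses `default_rng([seed, term_index])` over terms in sorted order;
subset-curve replicate chains use `default_rng([seed, replicate])`; and
evaluation seeds inside the curve are derived through `SeedSequence` from
(seed, replicate, size, k, method). Identical seeds reproduce tables
exactly.

The bioproject-subset curve grows, per replicate, a nested chain of
group subsets by seeded random addition (2 groups, then +1 per step) and
records the per-dataset mean AUROC of each requested (method, k) at each
evaluated size. Per-group HRR networks are cached across subsets and
replicates since they do not depend on the chain.

## Subnetworks and enrichment

A gene-centered network is the focus gene's first-degree neighborhood;
intersecting two neighborhoods gives the genes coexpressed with both
focus genes. Enrichment of a gene set uses the upper-tail hypergeometric
test; the default universe is the source network's node set (the
subnetworks are sampled from the network, so the network is the sampling
frame), with a genome-wide universe available by passing a different
gene set. Multiple testing is Benjamini–Hochberg, applied within each
annotation dataset separately, and terms are flagged enriched at
q < 0.1. BH was chosen for the q-value because it is the standard
step-up procedure; a Storey-style estimator is out of scope.

## Synthetic data

The generator emulates the *structure* the methods act on, not any real
transcriptome: several independent studies (groups), planted coexpressed
modules, length/depth confounding, and annotation terms tied to modules
plus random decoys.

Per active (module, group) pair, a standard-normal latent factor `f_s`
per sample drives the module genes' log-expression:
`x = log b_g + sd·(√r·f_s + √(1−r)·ε)`, giving log-scale within-module
correlation exactly `r` and the same marginal variance everywhere (so
module genes are not detectable by variance alone). Counts are
gamma-mixed Poisson (negative binomial) with mean proportional to
expression × gene length × sample depth.

Defaults describe the package's reference study design: 2000 genes, 5
groups × 10 libraries, 10 modules of 30 genes, within-module correlation
0.8, modules active in every group. Values with no externally given
scale were fixed once at realistic bulk-RNA-seq magnitudes: log-scale
biological SD 1.0, NB dispersion 0.05, gene lengths uniform 500–5000 bp,
sequencing depths log-uniform over one decade (≈3–30 M fragments, so
FPKM normalization is consequential), and baselines log-uniform over
0.05–200 with module genes floored at 1.0 so planted terms survive the
expression filter. One caveat worth knowing: FPKM is compositional, so
with a desk-scale gene count the realized FPKM values sit above the
baseline units; the weak tail of the baseline range is what gives the
filter work to do.

What passing tests on this generator do show: the inference machinery
recovers planted correlation structure, the evaluator is exact against
brute-force oracles and unbiased under label permutation, and
aggregation beats pooling when modules are condition-specific. What they
do not show: robustness to batch effects other than depth, to
non-Gaussian coexpression, to correlated background structure, or to the
annotation incompleteness of real functional databases.

## Numerical and degenerate-input choices

- Rank ties and top-k ties: lexicographic gene id, always — no RNG in
  network construction.
- `k ≥ G` requests return the complete graph with a warning.
- A sample with zero total counts, a gene without a length, duplicated
  ids, self-loops, non-numeric scores: all hard errors naming the
  offender.
- Empty filter results, empty term sets after filtering, and empty group
  sets are errors rather than silently empty outputs.
- All written artifacts use fixed float formatting (`%.10g`) and sorted
  canonical edge order (smaller gene id first), so reruns are
  byte-identical and diffs are meaningful.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data
at compact sizes chosen as the package's reference conditions: the
degree-floor check uses 700 genes at k ∈ {100, 300}; evaluator
correctness uses exhaustive oracles on ≤10-node networks plus 220
permuted terms; planted-signal recovery runs the full default design
(2000 genes, 5 × 10 libraries, COO at k = 100); the aggregation trend
uses 6 groups × 8 libraries with modules present in ~60 % of groups, 5
replicate chains, sizes 2 vs 6.

## Known limitations

- Pearson correlation only (no Spearman/mutual-information variants);
  the correlation is computed on untransformed FPKM.
- No node-degree bias correction in the evaluator and no
  multifunctionality analysis; degree–AUROC diagnostics are emitted as a
  table for external smoothing/plotting.
- Enrichment ignores ontology structure (no parent–child propagation).
- The on-disk edge-list dialect is this package's own; no attempt is
  made to read other tools' network formats.
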