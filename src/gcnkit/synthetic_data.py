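"""Synthetic multi-bioproject RNA-seq count data with planted coexpression modules.

The generator emulates the structure the toolkit consumes — several
independent studies (bioprojects) of bulk RNA-seq libraries, a shared gene
universe, and groups of genes (modules) whose expression co-varies — so
that every stage from normalization to enrichment is testable without any
download.  Per active (module, group) pair a latent per-sample factor
drives the module genes' log-means, inducing a chosen within-module
correlation; background genes fluctuate independently.  Counts are drawn
from an overdispersed (gamma-mixed Poisson, i.e. negative binomial)
distribution with per-gene lengths and per-sample sequencing depths, so
FPKM normalization is consequential.  One annotation term is planted per
module, alongside random decoy terms of the same size.

This is deliberately a structural emulation: it reproduces the levers the
methods act on (grouping, depth and length confounding, condition-specific
coexpression), not the biology of any real transcriptome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_expression import AnnotationCollection, CountMatrix, SampleTable
from .network_inference import Network, canonical_edge
from .normalize_filter import FpkmMatrix


@dataclass
class SyntheticConfig:
    """Study-design parameters of a simulated dataset.

    Defaults describe a compact multi-study design: 5 bioprojects of 10
    libraries, 2000 genes, 10 planted 30-gene modules with within-module
    correlation 0.8 active in every study.  ``module_presence_probability``
    below 1 makes modules condition-specific (active only in a random
    subset of studies), the regime in which aggregation pays off.
    """

    n_genes: int = 2000
    n_groups: int = 5
    samples_per_group: int = 10
    n_modules: int = 10
    module_size: int = 30
    within_module_correlation: float = 0.8
    module_presence_probability: float = 1.0
    noise_dispersion: float = 0.05
    gene_length_range: tuple[int, int] = (500, 5000)
    baseline_expression_range: tuple[float, float] = (0.05, 200.0)
    latent_sd: float = 1.0  # log-scale biological variability
    n_decoy_terms: int | None = None  # default: one per module
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules x {self.module_size} genes exceed the "
                f"{self.n_genes}-gene pool"
            )
        if not 0 < self.within_module_correlation < 1:
            raise ValueError("within_module_correlation must be in (0, 1)")
        if not 0 <= self.module_presence_probability <= 1:
            raise ValueError("module_presence_probability must be in [0, 1]")
        for lo, hi in (self.gene_length_range, self.baseline_expression_range):
            if lo <= 0 or hi <= lo:
                raise ValueError("ranges must be positive and increasing")
        if self.noise_dispersion <= 0 or self.latent_sd <= 0:
            raise ValueError("dispersion and latent_sd must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    modules: dict[str, frozenset[str]]
    active_groups: dict[str, frozenset[str]]
    term_for_module: dict[str, str]
    decoy_terms: frozenset[str] = field(default_factory=frozenset)

    def planted_terms(self) -> list[str]:
        return sorted(self.term_for_module.values())


def simulate_dataset(
    cfg: SyntheticConfig,
) -> tuple[CountMatrix, SampleTable, AnnotationCollection, SyntheticTruth]:
    """Draw a reproducible (counts, samples, annotations, truth) bundle.

    Module genes' log-expression is ``b_g + sd * (sqrt(r) * f_s +
    sqrt(1-r) * eps_gs)`` in groups where the module is active, with a
    shared latent factor ``f_s`` per sample, so their pairwise log-scale
    correlation is ``r``; everywhere else genes get independent noise of
    equal variance.  Baselines are relative expression levels, log-uniform
    over ``baseline_expression_range`` — a range spanning a weakly
    expressed tail so the low-expression filter has work to do; module
    genes are floored at 1.0, far above that tail, so planted terms
    survive filtering.  (The realized FPKM scale is compositional and so
    depends on the simulated gene count, not on these units directly.)
    Depths are log-uniform over one decade, and counts are gamma-Poisson
    with the configured dispersion.
    """
    rng = np.random.default_rng(cfg.seed)
    g, m, size = cfg.n_genes, cfg.n_modules, cfg.module_size
    n_samples = cfg.n_groups * cfg.samples_per_group
    r = cfg.within_module_correlation

    gene_ids = tuple(f"G{i:05d}" for i in range(g))
    group_ids = [f"BP{j:02d}" for j in range(1, cfg.n_groups + 1)]
    sample_ids = tuple(
        f"{gid}_S{j:02d}" for gid in group_ids for j in range(1, cfg.samples_per_group + 1)
    )
    sample_group = [gid for gid in group_ids for _ in range(cfg.samples_per_group)]

    lengths = rng.integers(
        cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=g
    )

    lo, hi = cfg.baseline_expression_range
    baselines = np.exp(rng.uniform(math.log(lo), math.log(hi), size=g))

    # disjoint modules drawn from the gene pool
    member_idx = rng.permutation(g)[: m * size]
    modules: dict[str, np.ndarray] = {
        f"M{j + 1:02d}": np.sort(member_idx[j * size : (j + 1) * size]) for j in range(m)
    }
    module_gene_mask = np.zeros(g, dtype=bool)
    module_gene_mask[member_idx] = True
    # module genes must be expressed for planted terms to survive filtering
    baselines[module_gene_mask] = np.maximum(baselines[module_gene_mask], 1.0)

    active: dict[str, frozenset[str]] = {}
    for mid in modules:
        mask = rng.random(cfg.n_groups) < cfg.module_presence_probability
        if not mask.any():
            mask[rng.integers(cfg.n_groups)] = True
        active[mid] = frozenset(gid for gid, a in zip(group_ids, mask) if a)

    # log-scale expression: baseline + shared factor (module, active group) + noise
    log_expr = np.tile(np.log(baselines)[:, None], (1, n_samples))
    noise = rng.standard_normal((g, n_samples))
    shared = np.zeros((g, n_samples))
    scale = np.ones((g, n_samples))  # sqrt(1-r) where a factor applies, else 1
    for mid, idx in modules.items():
        for j, gid in enumerate(group_ids):
            if gid not in active[mid]:
                continue
            cols = slice(j * cfg.samples_per_group, (j + 1) * cfg.samples_per_group)
            factor = rng.standard_normal(cfg.samples_per_group)
            shared[idx, cols] = math.sqrt(r) * factor[None, :]
            scale[idx, cols] = math.sqrt(1.0 - r)
    log_expr += cfg.latent_sd * (shared + scale * noise)
    rel = np.exp(log_expr)  # FPKM-scale relative expression

    # calibrate so each sample's expected total count matches its depth;
    # FPKM itself is invariant to this rescaling (it is compositional)
    kb = lengths / 1000.0
    per_sample_mass = (rel * kb[:, None]).sum(axis=0)
    rel *= 1e6 / per_sample_mass.mean()

    depths = 10 ** rng.uniform(6.5, 7.5, size=n_samples)  # mapped fragments
    mu = rel * kb[:, None] * (depths / 1e6)[None, :]
    shape = 1.0 / cfg.noise_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=counts,
        gene_lengths=lengths.astype(np.int64),
    )
    st = SampleTable(sample_ids=sample_ids, group_ids=tuple(sample_group))

    terms: dict[str, frozenset[str]] = {}
    term_for_module: dict[str, str] = {}
    for mid, idx in modules.items():
        term = f"TERM_{mid}"
        terms[term] = frozenset(gene_ids[i] for i in idx)
        term_for_module[mid] = term
    n_decoys = cfg.n_decoy_terms if cfg.n_decoy_terms is not None else m
    decoys = []
    for d in range(1, n_decoys + 1):
        pick = rng.choice(g, size=size, replace=False)
        term = f"DECOY_{d:02d}"
        terms[term] = frozenset(gene_ids[i] for i in pick)
        decoys.append(term)
    ann = AnnotationCollection(dataset_name="synthetic", terms=terms)
    truth = SyntheticTruth(
        modules={mid: frozenset(gene_ids[i] for i in idx) for mid, idx in modules.items()},
        active_groups=active,
        term_for_module=term_for_module,
        decoy_terms=frozenset(decoys),
    )
    return cm, st, ann, truth


def make_fixture(name: str):
    """Small deterministic bundles used across the test suite.

    * ``tiny`` — 6 genes x 8 samples (2 groups of 4) for smoke tests.
    * ``hrr_demo`` — a 6-gene x 8-sample FPKM matrix with a fixed seed,
      small enough for exhaustive rank/HRR checking.
    * ``gba_demo`` — an 8-node hand-built network with one planted 4-gene
      term (a clique) for exact AUROC oracles.
    * ``enrich_demo`` — a 20-gene universe, a 5-gene term and a matching
      5-gene query set for exact hypergeometric checking.
    """
    if name == "tiny":
        cfg = SyntheticConfig(
            n_genes=6,
            n_groups=2,
            samples_per_group=4,
            n_modules=1,
            module_size=3,
            within_module_correlation=0.9,
            baseline_expression_range=(5.0, 50.0),
            seed=11,
        )
        return simulate_dataset(cfg)
    if name == "hrr_demo":
        rng = np.random.default_rng(42)
        gene_ids = tuple(f"g{i}" for i in range(1, 7))
        base = rng.uniform(1.0, 4.0, size=(6, 8))
        base[1] = base[0] * 1.3 + rng.normal(0, 0.05, 8)  # g2 tracks g1
        base[3] = base[2] * 0.8 + rng.normal(0, 0.05, 8)  # g4 tracks g3
        return FpkmMatrix(
            gene_ids=gene_ids,
            sample_ids=tuple(f"s{i}" for i in range(1, 9)),
            fpkm=np.abs(base),
            provenance={"fixture": "hrr_demo"},
        )
    if name == "gba_demo":
        nodes = tuple(f"n{i}" for i in range(1, 9))
        clique = [("n1", "n2"), ("n1", "n3"), ("n1", "n4"), ("n2", "n3"),
                  ("n2", "n4"), ("n3", "n4")]
        ring = [("n5", "n6"), ("n6", "n7"), ("n7", "n8"), ("n5", "n8")]
        cross = [("n4", "n5"), ("n2", "n7")]
        edges = {canonical_edge(a, b): 1 for a, b in clique + ring + cross}
        net = Network(method="HRR", k=2, nodes=nodes, edges=edges)
        ann = AnnotationCollection(
            dataset_name="demo", terms={"T_CLIQUE": frozenset(["n1", "n2", "n3", "n4"])}
        )
        return net, ann
    if name == "enrich_demo":
        universe = frozenset(f"u{i:02d}" for i in range(1, 21))
        term = frozenset(["u01", "u02", "u03", "u04", "u05"])
        ann = AnnotationCollection(dataset_name="demo", terms={"T_HIT": term})
        return frozenset(term), ann, universe
    raise ValueError(f"unknown fixture {name!r}")
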