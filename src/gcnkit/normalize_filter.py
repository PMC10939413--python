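"""FPKM normalization, low-expression filtering, and per-bioproject grouping.

Counts are normalized once, from the raw count matrix, to fragments per
kilobase of transcript per million mapped fragments:

    FPKM[g, s] = counts[g, s] * 1e9 / (length_bp[g] * total_counts[s])

where ``total_counts[s]`` sums over all genes of the ingested matrix.
Grouped (per-bioproject) matrices restrict the columns of this one global
FPKM matrix — per-group totals are not recomputed — and are then
low-expression-filtered independently within each group, which lets genes
expressed only under specific conditions survive in their group even when
they fail the global filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_expression import CountMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class FpkmMatrix:
    """Normalized expression (genes x samples) with provenance of applied filters."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    fpkm: np.ndarray  # float64, shape (genes, samples)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.sample_ids = tuple(self.sample_ids)
        fpkm = np.asarray(self.fpkm, dtype=np.float64)
        if fpkm.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("fpkm shape does not match gene/sample ids")
        if (fpkm < 0).any():
            raise ValueError("fpkm must be non-negative")
        self.fpkm = fpkm

    @property
    def shape(self) -> tuple[int, int]:
        return self.fpkm.shape

    def restrict_samples(self, sample_ids: list[str]) -> "FpkmMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return FpkmMatrix(
            gene_ids=self.gene_ids,
            sample_ids=tuple(sample_ids),
            fpkm=self.fpkm[:, cols],
            provenance=dict(self.provenance, samples=f"subset({len(cols)})"),
        )


@dataclass
class GroupedExpression:
    """Per-bioproject FPKM matrices (independently filtered) plus the global matrix."""

    groups: dict[str, FpkmMatrix]
    source: FpkmMatrix
    min_libraries: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, fm in self.groups.items():
            samples = set(fm.sample_ids)
            if samples & seen:
                raise ValueError(f"group {gid!r} shares samples with another group")
            seen |= samples
            if len(fm.sample_ids) < self.min_libraries:
                raise ValueError(
                    f"group {gid!r} has {len(fm.sample_ids)} libraries "
                    f"(< {self.min_libraries})"
                )

    @property
    def group_ids(self) -> list[str]:
        return list(self.groups)


def fpkm_normalize(cm: CountMatrix) -> FpkmMatrix:
    """FPKM-normalize a count matrix; errors if any sample has zero total counts."""
    totals = cm.counts.sum(axis=0, dtype=np.float64)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample {cm.sample_ids[zero[0]]!r} has zero total counts")
    fpkm = cm.counts * 1e9 / (cm.gene_lengths[:, None].astype(np.float64) * totals[None, :])
    return FpkmMatrix(
        gene_ids=cm.gene_ids,
        sample_ids=cm.sample_ids,
        fpkm=fpkm,
        provenance={"normalization": "fpkm"},
    )


def filter_low_expression(
    fm: FpkmMatrix, min_fpkm: float = 0.5, min_fraction: float = 0.5
) -> FpkmMatrix:
    """Drop weakly and invariantly expressed genes.

    A gene is removed when the number of samples with FPKM below
    ``min_fpkm`` is at least ``min_fraction`` of the samples (inclusive at
    the boundary, i.e. survival requires adequate expression in a strict
    majority at the 0.5 default).  Zero-variance genes are additionally
    removed, since their Pearson correlation is undefined; their count is
    logged.  Surviving genes keep their original order.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    n_samples = fm.shape[1]
    n_low = (fm.fpkm < min_fpkm).sum(axis=1)
    keep = n_low < min_fraction * n_samples
    constant = np.ptp(fm.fpkm, axis=1) == 0
    n_constant = int((keep & constant).sum())
    if n_constant:
        logger.info("removed %d zero-variance gene(s)", n_constant)
    keep &= ~constant
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    idx = np.flatnonzero(keep)
    return FpkmMatrix(
        gene_ids=tuple(fm.gene_ids[i] for i in idx),
        sample_ids=fm.sample_ids,
        fpkm=fm.fpkm[idx, :],
        provenance=dict(
            fm.provenance,
            low_expression_filter=f"min_fpkm={min_fpkm},min_fraction={min_fraction}",
        ),
    )


def group_by_bioproject(
    cm: CountMatrix,
    st: SampleTable,
    min_libraries: int = 6,
    min_fpkm: float = 0.5,
    min_fraction: float = 0.5,
) -> GroupedExpression:
    """Split samples by bioproject, drop small groups, filter each group independently.

    Groups with fewer than ``min_libraries`` samples are dropped (the
    aggregation unit must carry enough libraries for stable correlations).
    Normalization happens once on the full matrix; each retained group's
    columns are then low-expression-filtered within the group.
    """
    group_map = st.group_map
    missing = [s for s in cm.sample_ids if s not in group_map]
    if missing:
        raise KeyError(f"sample(s) missing from sample table: {missing[:5]}")
    fm = fpkm_normalize(cm)

    by_group: dict[str, list[str]] = {}
    for s in cm.sample_ids:
        by_group.setdefault(group_map[s], []).append(s)

    groups: dict[str, FpkmMatrix] = {}
    for gid, samples in by_group.items():
        if len(samples) < min_libraries:
            logger.info(
                "dropping group %s (%d < %d libraries)", gid, len(samples), min_libraries
            )
            continue
        sub = fm.restrict_samples(samples)
        try:
            groups[gid] = filter_low_expression(sub, min_fpkm, min_fraction)
        except ValueError:
            logger.warning("group %s lost every gene to filtering; dropped", gid)
    if not groups:
        raise ValueError(
            f"no bioproject group with >= {min_libraries} libraries survived"
        )
    return GroupedExpression(groups=groups, source=fm, min_libraries=min_libraries)
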