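"""Readers/writers for count matrices, sample tables, gene-set annotations and networks.

All tabular formats are tab-separated UTF-8 text; lines starting with ``#``
are comments.  Gene identifiers are treated as opaque strings (no id
translation between annotation versions is attempted).  Undirected network
edges are stored once with the lexicographically smaller gene first, so
written files diff deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network_inference import Network, canonical_edge

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates the expected tabular format."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CountMatrix:
    """Gene-level fragment counts (genes x samples) with per-gene lengths in bp."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # int64, shape (genes, samples)
    gene_lengths: np.ndarray  # int64, shape (genes,)

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.sample_ids = tuple(self.sample_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicated gene id(s) in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicated sample id(s) in count matrix")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise FormatError("counts must be integral")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise FormatError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        lengths = np.asarray(self.gene_lengths)
        if lengths.shape != (len(self.gene_ids),):
            raise FormatError("one gene length per gene is required")
        if not np.issubdtype(lengths.dtype, np.integer) or (lengths <= 0).any():
            raise FormatError("gene lengths must be positive integers (bp)")
        self.gene_lengths = lengths.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleTable:
    """Sample metadata: id, bioproject/group id, optional organ, extra columns kept."""

    sample_ids: tuple[str, ...]
    group_ids: tuple[str, ...]
    organs: tuple[str | None, ...] | None = None
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.group_ids = tuple(self.group_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicated sample id(s) in sample table")
        if len(self.group_ids) != len(self.sample_ids):
            raise FormatError("sample and group columns differ in length")
        if any(not g for g in self.group_ids):
            raise FormatError("empty group id in sample table")

    @property
    def group_map(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.group_ids))

    def samples_in_group(self, group_id: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group_ids) if g == group_id]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_ids:
            seen.setdefault(g)
        return list(seen)


@dataclass
class AnnotationCollection:
    """A named functional-annotation dataset: term id -> gene set."""

    dataset_name: str
    terms: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise FormatError(f"term {term!r} has an empty gene set")
            self.terms[term] = frozenset(genes)

    @property
    def n_terms(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# readers


def read_count_matrix(counts_path: str | Path, lengths_path: str | Path) -> CountMatrix:
    """Read a genes x samples count TSV plus a gene-length TSV.

    The count file has a header row of sample ids and gene ids in the first
    column.  The length file maps gene id -> length in bp (an optional
    header row is detected and skipped).  Every gene in the count matrix
    must have a length.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise FormatError(f"{counts_path}: empty count matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{counts_path}: duplicated gene id {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        dup = df.columns[pd.Index(df.columns).duplicated()][0]
        raise FormatError(f"{counts_path}: duplicated sample id {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{counts_path}: non-numeric count value")

    ldf = pd.read_csv(
        lengths_path, sep="\t", comment="#", header=None, names=["gene_id", "length"],
        dtype={"gene_id": str},
    )
    if ldf.empty:
        raise FormatError(f"{lengths_path}: empty gene-length table")
    try:
        float(ldf.iloc[0, 1])
    except (TypeError, ValueError):
        ldf = ldf.iloc[1:]  # header row
    if ldf["gene_id"].duplicated().any():
        dup = ldf["gene_id"][ldf["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"{lengths_path}: duplicated gene id {dup!r}")
    length_map = dict(zip(ldf["gene_id"], pd.to_numeric(ldf["length"])))
    missing = [g for g in df.index if g not in length_map]
    if missing:
        raise KeyError(f"gene(s) missing from length table: {missing[:5]}")
    lengths = np.array([length_map[g] for g in df.index])
    if not np.allclose(lengths, np.rint(lengths)):
        raise FormatError(f"{lengths_path}: gene lengths must be integers")
    return CountMatrix(
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        counts=values,
        gene_lengths=np.rint(lengths).astype(np.int64),
    )


def read_sample_table(path: str | Path) -> SampleTable:
    """Read sample metadata (columns ``sample_id``, ``group_id``, optional ``organ``).

    Row order is preserved; unknown extra columns are retained but ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "group_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated sample id {dup!r}")
    if df["group_id"].isna().any() or (df["group_id"].str.len() == 0).any():
        raise FormatError(f"{path}: empty group id")
    organs: tuple[str | None, ...] | None = None
    if "organ" in df.columns:
        organs = tuple(None if pd.isna(v) else str(v) for v in df["organ"])
    extra_cols = [c for c in df.columns if c not in ("sample_id", "group_id", "organ")]
    extra = df[extra_cols].copy() if extra_cols else None
    return SampleTable(
        sample_ids=tuple(df["sample_id"]),
        group_ids=tuple(df["group_id"]),
        organs=organs,
        extra=extra,
    )


def read_annotations(
    path: str | Path, format: str = "gmt", dataset_name: str = "annotations"
) -> AnnotationCollection:
    """Read a gene-set collection from GMT or two-column (gene, term) TSV.

    Duplicate (gene, term) pairs are deduplicated silently; terms left with
    zero genes are dropped with a logged warning.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    if format == "gmt":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: malformed GMT line {line[:40]!r}")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                logger.warning("term %r has no genes; dropped", term)
                continue
            terms.setdefault(term, set()).update(genes)
            if desc:
                labels[term] = desc
    elif format == "tsv":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=["gene", "term"], dtype=str
        )
        if not df.empty and df.iloc[0].tolist() == ["gene", "term"]:
            df = df.iloc[1:]
        for gene, term in zip(df["gene"], df["term"]):
            if pd.isna(gene) or pd.isna(term):
                raise FormatError(f"{path}: incomplete (gene, term) row")
            terms.setdefault(term, set()).add(gene)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not terms:
        raise FormatError(f"{path}: no terms parsed")
    return AnnotationCollection(
        dataset_name=dataset_name,
        terms={t: frozenset(g) for t, g in terms.items()},
        labels=labels,
    )


def write_annotations(ann: AnnotationCollection, path: str | Path) -> None:
    """Write a collection as GMT (terms and member genes in sorted order)."""
    lines = []
    for term in sorted(ann.terms):
        desc = ann.labels.get(term, ann.dataset_name)
        lines.append("\t".join([term, desc, *sorted(ann.terms[term])]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# network edge lists


def write_network(network: Network, path: str | Path) -> None:
    """Write an edge-list TSV with a commented key=value header block."""
    from . import __version__

    lines = [
        f"# package=gcnkit {__version__}",
        "# format=network-v1",
        f"# method={network.method}",
        f"# k={network.k}",
        "# score=" + ("hrr" if network.method == "HRR" else "co-occurrence-frequency"),
    ]
    if network.n_groups is not None:
        lines.append(f"# n_groups={network.n_groups}")
    lines.append("gene_a\tgene_b\tscore")
    for (a, b) in sorted(network.edges):
        lines.append(f"{a}\t{b}\t{network.edges[(a, b)]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> Network:
    """Read an edge-list TSV written by :func:`write_network`."""
    meta: dict[str, str] = {}
    edges: dict[tuple[str, str], int] = {}
    nodes: set[str] = set()
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: malformed edge row {line[:40]!r}")
        a, b, score = parts
        if a == b:
            raise FormatError(f"{path}: self-loop on gene {a!r}")
        try:
            s = float(score)
        except ValueError:
            raise FormatError(f"{path}: non-numeric score {score!r}") from None
        if s != int(s):
            raise FormatError(f"{path}: non-integer score {score!r}")
        edges[canonical_edge(a, b)] = int(s)
        nodes.update((a, b))
    if "method" not in meta or "k" not in meta:
        raise FormatError(f"{path}: missing method/k header")
    n_groups = int(meta["n_groups"]) if "n_groups" in meta else None
    return Network(
        method=meta["method"],
        k=int(meta["k"]),
        nodes=tuple(sorted(nodes)),
        edges=edges,
        n_groups=n_groups,
    )


# ---------------------------------------------------------------------------
# generic matrix round-trip (FPKM and count tables written by the CLI)


def write_matrix(
    gene_ids: Iterable[str],
    sample_ids: Iterable[str],
    values: np.ndarray,
    path: str | Path,
    header_meta: Mapping[str, object] | None = None,
    float_format: str = "%.10g",
) -> None:
    df = pd.DataFrame(values, index=list(gene_ids), columns=list(sample_ids))
    df.index.name = "gene_id"
    with open(path, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", float_format=float_format)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
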