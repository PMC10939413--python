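"""Coexpression network inference from a filtered FPKM matrix.

Two network-building strategies are provided:

* **HRR** — for every gene pair, partners are ranked by descending Pearson
  correlation (PCC) and the highest reciprocal rank
  ``HRR(x, y) = max(rank(x, y), rank(y, x))`` is taken as the edge score
  (lower = stronger reciprocal coexpression).  The network at sparsity ``k``
  is the undirected union of every gene's ``k`` best partners by ascending
  HRR, so each node has degree at least ``k`` while hub nodes can greatly
  exceed it.
* **COO** — per-study (bioproject) HRR networks are aggregated by counting,
  for each gene pair, in how many study networks the edge occurs
  (its co-occurrence frequency).  Each gene then keeps its ``k`` best
  partners by descending frequency.  Edges recurring across independent
  studies are condition-robust; edges present in a single study capture
  condition-specific coexpression that pooled correlation dilutes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    import networkx

    from .normalize_filter import FpkmMatrix

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Return the undirected edge key with the lexicographically smaller id first."""
    if a == b:
        raise ValueError(f"self-loop on gene {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class RankStructure:
    """Per-gene partner ranks by descending PCC.

    ``ranks[i, j]`` is the 1-based position of gene ``j`` in gene ``i``'s
    partner list sorted by descending PCC (self excluded, diagonal 0).
    Ties are broken by lexicographic gene id so ranks are reproducible.
    ``pcc`` is the symmetric Pearson correlation matrix.
    """

    gene_ids: tuple[str, ...]
    pcc: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        g = len(self.gene_ids)
        if self.pcc.shape != (g, g) or self.ranks.shape != (g, g):
            raise ValueError("pcc/ranks shape does not match gene count")

    def rank(self, x: str, y: str) -> int:
        i, j = self.gene_ids.index(x), self.gene_ids.index(y)
        return int(self.ranks[i, j])


@dataclass
class HrrMatrix:
    """Symmetric highest-reciprocal-rank matrix (diagonal 0)."""

    gene_ids: tuple[str, ...]
    hrr: np.ndarray

    def value(self, x: str, y: str) -> int:
        i, j = self.gene_ids.index(x), self.gene_ids.index(y)
        return int(self.hrr[i, j])


@dataclass
class Network:
    """Undirected weighted coexpression network.

    Edge keys are canonical (lexicographically smaller gene first); scores
    are the HRR value for HRR networks and the co-occurrence frequency
    (an integer in ``[1, n_groups]``) for COO networks.
    """

    method: str  # "HRR" | "COO"
    k: int
    nodes: tuple[str, ...]
    edges: dict[Edge, int]
    n_groups: int | None = None
    _adj: dict[str, set[str]] | None = field(
        default=None, repr=False, compare=False, init=False
    )

    def __post_init__(self) -> None:
        if self.method not in ("HRR", "COO"):
            raise ValueError(f"unknown network method {self.method!r}")
        node_set = set(self.nodes)
        for (a, b), s in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on gene {a!r}")
            if a > b:
                raise ValueError(f"non-canonical edge key ({a!r}, {b!r})")
            if s <= 0:
                raise ValueError(f"non-positive score on edge ({a}, {b})")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {g: set() for g in self.nodes}
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            self._adj = adj
        return self._adj

    def neighbors(self, gene: str) -> set[str]:
        adj = self.adjacency()
        if gene not in adj:
            raise KeyError(f"gene {gene!r} is not a node of this network")
        return adj[gene]

    def degrees(self) -> dict[str, int]:
        return {g: len(nbrs) for g, nbrs in self.adjacency().items()}

    def to_networkx(self) -> "networkx.Graph":
        import networkx as nx

        g = nx.Graph(method=self.method, k=self.k)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((a, b, s) for (a, b), s in self.edges.items())
        return g


def _lex_keys(gene_ids: Sequence[str]) -> np.ndarray:
    """Integer sort key per gene: position of its id in lexicographic order."""
    keys = np.empty(len(gene_ids), dtype=np.int64)
    keys[np.argsort(np.asarray(gene_ids, dtype=object))] = np.arange(len(gene_ids))
    return keys


def pcc_rank(fm: "FpkmMatrix") -> RankStructure:
    """Compute pairwise PCC over samples and per-gene descending-PCC ranks.

    Requires at least 3 samples and no zero-variance genes (the
    low-expression filter removes those).  Equal PCC values are ranked by
    lexicographic gene id so the result is platform-independent.
    """
    x = np.asarray(fm.fpkm, dtype=np.float64)
    gene_ids = tuple(fm.gene_ids)
    g, s = x.shape
    if s < 3:
        raise ValueError(f"PCC ranking needs >= 3 samples, got {s}")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [gene_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"zero-variance gene(s) encountered (e.g. {bad}); filter first")
    pcc = np.corrcoef(x)
    np.clip(pcc, -1.0, 1.0, out=pcc)

    lex = _lex_keys(gene_ids)
    ranks = np.zeros((g, g), dtype=np.int32)
    positions = np.empty(g, dtype=np.int32)
    for i in range(g):
        order = np.lexsort((lex, -pcc[i]))  # descending PCC, ties by gene id
        order = order[order != i]
        positions[order] = np.arange(1, g, dtype=np.int32)
        ranks[i, :] = positions
        ranks[i, i] = 0
    return RankStructure(gene_ids=gene_ids, pcc=pcc, ranks=ranks)


def hrr_scores(rs: RankStructure) -> HrrMatrix:
    """Symmetric HRR matrix: elementwise max of the rank matrix and its transpose."""
    hrr = np.maximum(rs.ranks, rs.ranks.T)
    np.fill_diagonal(hrr, 0)
    return HrrMatrix(gene_ids=rs.gene_ids, hrr=hrr)


def build_hrr_network(hm: HrrMatrix, k: int, strict_mutual: bool = False) -> Network:
    """Build the HRR network at sparsity ``k``.

    Default semantics: the undirected union of each gene's ``k`` best
    partners by ascending HRR (ties by HRR then lexicographic gene id), so
    minimum degree equals ``min(k, G-1)`` while hubs may far exceed ``k``.
    ``strict_mutual=True`` instead keeps only edges with ``HRR <= k``
    (both ranks within the top ``k``), a sparser variant for comparison.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gene_ids = hm.gene_ids
    g = len(gene_ids)
    hrr = hm.hrr

    if strict_mutual:
        edges: dict[Edge, int] = {}
        ii, jj = np.nonzero((hrr <= k) & (hrr > 0))
        for i, j in zip(ii.tolist(), jj.tolist()):
            if i < j:
                edges[canonical_edge(gene_ids[i], gene_ids[j])] = int(hrr[i, j])
        return Network(method="HRR", k=k, nodes=gene_ids, edges=edges)

    if k >= g:
        warnings.warn(
            f"sparsity k={k} >= number of genes ({g}); returning the complete graph",
            stacklevel=2,
        )
        k = g - 1

    lex = _lex_keys(gene_ids)
    work = hrr.astype(np.int64, copy=True)
    np.fill_diagonal(work, np.iinfo(np.int64).max)  # never select self
    selected: set[tuple[int, int]] = set()
    for i in range(g):
        order = np.lexsort((lex, work[i]))[:k]
        for j in order.tolist():
            selected.add((i, j) if i < j else (j, i))
    edges = {
        canonical_edge(gene_ids[i], gene_ids[j]): int(hrr[i, j]) for i, j in selected
    }
    return Network(method="HRR", k=k, nodes=gene_ids, edges=edges)


def build_coo_network(group_networks: Sequence[Network], k: int) -> Network:
    """Aggregate per-group HRR networks into a co-occurrence (COO) network.

    Edge frequency = number of group networks containing the edge.  Each
    gene keeps its ``k`` best partners by descending frequency; frequency
    ties are broken by lower mean HRR across the groups containing the
    edge, then by lexicographic partner id.  The node universe is the
    union of the group node sets, so genes expressed only under specific
    conditions remain in the aggregated network.
    """
    if len(group_networks) < 2:
        raise ValueError("co-occurrence aggregation needs >= 2 group networks")
    for net in group_networks:
        if net.method != "HRR":
            raise ValueError("group networks must be HRR networks")
        if net.k != k:
            raise ValueError(
                f"group network built at k={net.k}, aggregation requested at k={k}"
            )

    freq: dict[Edge, int] = {}
    hrr_sum: dict[Edge, int] = {}
    nodes: set[str] = set()
    for net in group_networks:
        nodes.update(net.nodes)
        for e, s in net.edges.items():
            freq[e] = freq.get(e, 0) + 1
            hrr_sum[e] = hrr_sum.get(e, 0) + s
    if not freq:
        raise ValueError("no edges in any group network")

    adj: dict[str, list[str]] = {g: [] for g in nodes}
    for a, b in freq:
        adj[a].append(b)
        adj[b].append(a)

    node_tuple = tuple(sorted(nodes))
    selected: set[Edge] = set()
    for gene in node_tuple:
        cands = adj[gene]
        cands.sort(
            key=lambda p: (
                -freq[e := canonical_edge(gene, p)],
                hrr_sum[e] / freq[e],
                p,
            )
        )
        for p in cands[:k]:
            selected.add(canonical_edge(gene, p))

    edges = {e: freq[e] for e in selected}
    logger.info(
        "COO aggregation: %d groups, %d nodes, %d candidate edges, %d retained",
        len(group_networks), len(nodes), len(freq), len(edges),
    )
    return Network(
        method="COO", k=k, nodes=node_tuple, edges=edges, n_groups=len(group_networks)
    )


def hrr_network_from_fpkm(fm: "FpkmMatrix", k: int, strict_mutual: bool = False) -> Network:
    """Convenience chain: PCC ranks -> HRR scores -> HRR network."""
    return build_hrr_network(hrr_scores(pcc_rank(fm)), k, strict_mutual=strict_mutual)
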