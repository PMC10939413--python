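"""Degree statistics and degree distributions of coexpression networks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_inference import Network


@dataclass
class TopologySummary:
    n_nodes: int
    degree_min: int
    degree_max: int
    degree_range: int
    degree_mean: float
    pct_of_genome: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def degree_stats(net: Network, genome_gene_total: int | None = None) -> TopologySummary:
    """Exact node-degree statistics; optionally the share of an annotated genome.

    The minimum degree of a union-of-top-k network equals the sparsity
    threshold k whenever the gene count exceeds k; hubs push the maximum
    far above it.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.to_networkx()
    degrees = np.array([d for _, d in g.degree()], dtype=np.int64)
    pct = None
    if genome_gene_total is not None:
        if genome_gene_total <= 0:
            raise ValueError("genome_gene_total must be positive")
        pct = 100.0 * net.n_nodes / genome_gene_total
    return TopologySummary(
        n_nodes=net.n_nodes,
        degree_min=int(degrees.min()),
        degree_max=int(degrees.max()),
        degree_range=int(degrees.max() - degrees.min()),
        degree_mean=float(degrees.mean()),
        pct_of_genome=pct,
    )


def degree_distribution(net: Network, n_bins: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Histogram of node degrees plus the raw degree vector for external plotting.

    Returns a table with columns ``bin_left``, ``bin_right``, ``count``
    whose counts sum to the node count.  Bimodality of aggregated-network
    degree distributions is a descriptive observation on this histogram;
    no formal test is applied.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    g = net.to_networkx()
    degrees = np.array([d for _, d in g.degree()], dtype=np.int64)
    counts, edges = np.histogram(degrees, bins=n_bins)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return table, degrees
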