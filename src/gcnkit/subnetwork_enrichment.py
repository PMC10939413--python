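"""Gene-centered subnetworks and hypergeometric gene-set enrichment.

A gene-centered network is the set of first-degree neighbors of a focus
gene; intersecting two such neighborhoods isolates genes coexpressed with
both focus genes.  Enrichment of a gene set against an annotation
collection uses the upper-tail hypergeometric test with the source
network's node set as the default sampling universe (the subnetworks are
drawn from the network, so the network is the natural frame; a genome-wide
universe can be supplied instead).  Multiple testing is controlled with
Benjamini–Hochberg within each annotation dataset separately, and terms
are called enriched below a q-value threshold (0.1 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_expression import AnnotationCollection
from .network_inference import Network

logger = logging.getLogger(__name__)


@dataclass
class GeneCenteredNetwork:
    """First-degree neighborhood of a focus gene (focus excluded)."""

    focus_gene: str
    members: frozenset[str]
    source: Network

    def __post_init__(self) -> None:
        if self.focus_gene in self.members:
            raise ValueError("focus gene cannot be its own neighbor")

    @property
    def n_members(self) -> int:
        return len(self.members)


def gene_centered_network(net: Network, gene: str) -> GeneCenteredNetwork:
    """Extract the first-degree neighborhood of ``gene``."""
    if gene not in net.adjacency():
        raise KeyError(f"gene {gene!r} is not a node of the network")
    return GeneCenteredNetwork(
        focus_gene=gene, members=frozenset(net.neighbors(gene)), source=net
    )


def intersect_subnetworks(a: GeneCenteredNetwork, b: GeneCenteredNetwork) -> frozenset[str]:
    """Genes coexpressed with both focus genes (requires the same source network)."""
    if a.source is not b.source and a.source != b.source:
        raise ValueError("subnetworks come from different source networks")
    shared = a.members & b.members
    if not shared:
        logger.info(
            "neighborhoods of %s and %s are disjoint", a.focus_gene, b.focus_gene
        )
    return frozenset(shared)


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    genes: set[str] | frozenset[str],
    ann: AnnotationCollection,
    universe: set[str] | frozenset[str],
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``genes`` within ``universe``.

    For each term with at least one gene in the universe, the p-value is
    the probability of observing at least the seen overlap when drawing
    ``|genes|`` genes without replacement from the universe.  q-values are
    BH-adjusted across the terms of this collection; ``enriched`` flags
    q < ``q_threshold``.
    """
    genes = frozenset(genes)
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    if not genes <= universe:
        stray = sorted(genes - universe)[:5]
        raise ValueError(f"gene set not contained in universe (e.g. {stray})")

    m_universe = len(universe)
    n_drawn = len(genes)
    records = []
    for term in sorted(ann.terms):
        term_in_universe = ann.terms[term] & universe
        if not term_in_universe:
            logger.debug("term %r has no gene in the universe; skipped", term)
            continue
        overlap = len(term_in_universe & genes)
        p = float(
            hypergeom.sf(overlap - 1, m_universe, len(term_in_universe), n_drawn)
        )
        records.append(
            {
                "dataset_name": ann.dataset_name,
                "term_id": term,
                "n_term_in_universe": len(term_in_universe),
                "n_term_in_set": overlap,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "dataset_name", "term_id", "n_term_in_universe", "n_term_in_set", "p_value",
        ],
    )
    if table.empty:
        return table.assign(q_value=pd.Series(dtype=float), enriched=pd.Series(dtype=bool))
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["enriched"] = table["q_value"] < q_threshold
    return table


def enrich_collections(
    genes: set[str] | frozenset[str],
    collections: list[AnnotationCollection],
    universe: set[str] | frozenset[str],
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Enrichment over several annotation datasets, BH-corrected within each."""
    tables = [
        hypergeometric_enrichment(genes, ann, universe, q_threshold)
        for ann in collections
    ]
    return pd.concat(tables, ignore_index=True)
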