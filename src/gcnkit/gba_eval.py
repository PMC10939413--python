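"""Guilt-by-association evaluation of coexpression networks by neighbor voting.

A network is useful for function prediction to the extent that genes
sharing a functional annotation are neighbors.  Neighbor voting quantifies
this: for each annotation term, the annotated genes are split into
cross-validation folds; with one fold hidden, every gene is scored by the
fraction of its direct neighbors that carry the (training) annotation —

    votes(g) = |neighbors(g) ∩ training positives| / degree(g)

— and the hidden positives are ranked among all non-training genes.  The
area under the ROC curve of that ranking (computed through the
Mann–Whitney rank-sum identity with mid-rank ties) is averaged over folds
to give the term's AUROC; 0.5 is chance, 1.0 perfect, and 0.7 is the
conventional bar for an acceptably predictive network.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .io_expression import AnnotationCollection
from .network_inference import Network, build_coo_network, hrr_network_from_fpkm
from .normalize_filter import FpkmMatrix, GroupedExpression, filter_low_expression

logger = logging.getLogger(__name__)


def filter_terms(
    ann: AnnotationCollection,
    net: Network,
    min_size: int = 20,
    max_size: int = 1000,
) -> AnnotationCollection:
    """Intersect term gene-sets with network nodes, then keep sizes in [min, max].

    Small terms give unstable AUROC estimates and very large ones approach
    the network size; both ends are excluded before evaluation.
    """
    nodes = set(net.nodes)
    kept: dict[str, frozenset[str]] = {}
    for term, genes in ann.terms.items():
        present = frozenset(g for g in genes if g in nodes)
        if min_size <= len(present) <= max_size:
            kept[term] = present
    if not kept:
        raise ValueError(
            f"no term of {ann.dataset_name!r} has {min_size}-{max_size} genes in the network"
        )
    return AnnotationCollection(
        dataset_name=ann.dataset_name,
        terms=kept,
        labels={t: ann.labels[t] for t in kept if t in ann.labels},
    )


def roc_auc_from_scores(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUROC of a score vector via the rank-sum identity (mid-rank ties)."""
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)
    rank_sum = float(ranks[positive].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _term_folds(
    rng: np.random.Generator, positives: np.ndarray, n_folds: int
) -> list[np.ndarray]:
    """Seeded partition of a term's gene indices into near-equal folds."""
    return [f for f in np.array_split(rng.permutation(positives), n_folds)]


def neighbor_voting_auroc(
    net: Network,
    ann: AnnotationCollection,
    n_folds: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated neighbor-voting AUROC for every term of a collection.

    Genes annotated to a term but absent from the network are excluded
    (they are unrankable); terms with fewer member genes than folds are
    skipped with a warning.  Fold assignment is seeded per term through
    ``default_rng([seed, term_index])`` with terms enumerated in sorted
    order, so a single integer seed fixes the whole evaluation.

    Returns a table with columns dataset_name, term_id, n_genes, auroc,
    mean_degree (the average network degree of the term's genes).
    """
    node_index = {g: i for i, g in enumerate(net.nodes)}
    n = len(net.nodes)
    rows_idx: list[int] = []
    cols_idx: list[int] = []
    for a, b in net.edges:
        ia, ib = node_index[a], node_index[b]
        rows_idx += [ia, ib]
        cols_idx += [ib, ia]
    adjacency = sparse.csr_matrix(
        (np.ones(len(rows_idx), dtype=np.float64), (rows_idx, cols_idx)), shape=(n, n)
    )
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    if (degrees == 0).any():
        raise ValueError("network contains isolated nodes; cannot vote")

    records = []
    for term_index, term in enumerate(sorted(ann.terms)):
        members = np.array(
            sorted(node_index[g] for g in ann.terms[term] if g in node_index),
            dtype=np.int64,
        )
        if len(members) < n_folds:
            logger.warning(
                "term %r has %d network genes (< %d folds); skipped",
                term, len(members), n_folds,
            )
            continue
        rng = np.random.default_rng([seed, term_index])
        fold_aurocs = []
        for fold in _term_folds(rng, members, n_folds):
            train = np.setdiff1d(members, fold)
            indicator = np.zeros(n, dtype=np.float64)
            indicator[train] = 1.0
            votes = adjacency.dot(indicator) / degrees
            eval_mask = np.ones(n, dtype=bool)
            eval_mask[train] = False
            positive = np.zeros(n, dtype=bool)
            positive[fold] = True
            fold_aurocs.append(
                roc_auc_from_scores(votes[eval_mask], positive[eval_mask])
            )
        records.append(
            {
                "dataset_name": ann.dataset_name,
                "term_id": term,
                "n_genes": len(members),
                "auroc": float(np.mean(fold_aurocs)),
                "mean_degree": float(degrees[members].mean()),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["dataset_name", "term_id", "n_genes", "auroc", "mean_degree"]
    )


def dataset_mean_auroc(rows: pd.DataFrame) -> tuple[pd.Series, float]:
    """Unweighted mean term AUROC per dataset plus the grand average across datasets."""
    if rows.empty:
        raise ValueError("no term AUROC rows")
    per_dataset = rows.groupby("dataset_name")["auroc"].mean()
    return per_dataset, float(per_dataset.mean())


def term_degree_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Join of term id, mean network degree of its genes and its AUROC.

    Intended for downstream smoothing/plotting of the degree-vs-AUROC
    relationship; no smoothing is performed here.
    """
    return rows[["dataset_name", "term_id", "mean_degree", "auroc"]].copy()


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def bioproject_subset_curve(
    ge: GroupedExpression,
    anns: AnnotationCollection | Sequence[AnnotationCollection],
    methods: Iterable[str] = ("HRR", "COO"),
    k_values: Iterable[int] = (100, 300),
    sizes: Iterable[int] | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    n_folds: int = 3,
    min_term_size: int = 20,
    max_term_size: int = 1000,
    min_fpkm: float = 0.5,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean AUROC as a function of the number of aggregated bioprojects.

    For each replicate a nested chain of group subsets is grown by seeded
    random addition: 2 groups, then one more per step up to the largest
    requested size.  At every evaluated size and for every requested
    (method, k), a network is built from the subset — COO by aggregating
    the per-group HRR networks, HRR by pooling the subset's libraries into
    one matrix — and the per-dataset mean neighbor-voting AUROC recorded.

    Returns one row per (n_groups, replicate, method, k, dataset).
    """
    if isinstance(anns, AnnotationCollection):
        anns = [anns]
    methods = sorted(set(methods))
    for m in methods:
        if m not in ("HRR", "COO"):
            raise ValueError(f"unknown method {m!r}")
    k_values = sorted(set(int(k) for k in k_values))
    group_ids = sorted(ge.groups)
    n_available = len(group_ids)
    sizes = sorted(set(sizes)) if sizes is not None else list(range(2, n_available + 1))
    if sizes[0] < 2 or sizes[-1] > n_available:
        raise ValueError(
            f"subset sizes must lie in [2, {n_available}], got {sizes[0]}..{sizes[-1]}"
        )

    # Per-group HRR networks do not depend on the replicate chain: build once.
    group_nets: dict[tuple[int, str], Network] = {}
    if "COO" in methods:
        for k in k_values:
            for gid in group_ids:
                group_nets[(k, gid)] = hrr_network_from_fpkm(ge.groups[gid], k)

    records = []
    for rep in range(1, n_replicates + 1):
        chain = list(np.random.default_rng([seed, rep]).permutation(group_ids))
        for size in sizes:
            subset = chain[:size]
            for k in k_values:
                nets: dict[str, Network] = {}
                if "COO" in methods:
                    nets["COO"] = build_coo_network(
                        [group_nets[(k, gid)] for gid in subset], k
                    )
                if "HRR" in methods:
                    samples = [
                        s for gid in subset for s in ge.groups[gid].sample_ids
                    ]
                    pooled = filter_low_expression(
                        ge.source.restrict_samples(samples), min_fpkm, min_fraction
                    )
                    nets["HRR"] = hrr_network_from_fpkm(pooled, k)
                for method, net in sorted(nets.items()):
                    for ann in anns:
                        eval_seed = _derived_seed(
                            seed, rep, size, k, 0 if method == "HRR" else 1
                        )
                        filtered = filter_terms(ann, net, min_term_size, max_term_size)
                        table = neighbor_voting_auroc(
                            net, filtered, n_folds=n_folds, seed=eval_seed
                        )
                        records.append(
                            {
                                "n_groups": size,
                                "replicate": rep,
                                "method": method,
                                "k": k,
                                "dataset_name": ann.dataset_name,
                                "mean_auroc": float(table["auroc"].mean()),
                            }
                        )
    return pd.DataFrame.from_records(records)
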