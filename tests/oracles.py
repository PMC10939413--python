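"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's vectorized code paths:
rankings by explicit sorting, AUROC by pairwise comparison or explicit
threshold-sweep ROC integration, BH by the textbook step-up recursion,
and network construction by exhaustive enumeration of per-gene best-k
lists.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pairwise_auroc(pos_scores, neg_scores) -> float:
    """P(score_pos > score_neg) + 0.5 P(equal), by full double loop."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def roc_integrate(pos_scores, neg_scores) -> float:
    """Exact ROC area by threshold sweep and trapezoidal integration."""
    thresholds = sorted(set(pos_scores) | set(neg_scores), reverse=True)
    points = [(0.0, 0.0)]
    for t in thresholds:
        fpr = sum(1 for s in neg_scores if s >= t) / len(neg_scores)
        tpr = sum(1 for s in pos_scores if s >= t) / len(pos_scores)
        points.append((fpr, tpr))
    area = 0.0
    for (x1, y1), (x2, y2) in zip(points, points[1:]):
        area += (x2 - x1) * (y1 + y2) / 2.0
    return area


def neighbor_voting_oracle(net, term_genes, n_folds, seed, term_index) -> float:
    """Cross-validated neighbor-voting AUROC by explicit loops.

    Mirrors the documented seeding contract (fold assignment from
    ``default_rng([seed, term_index])`` over sorted member indices) but
    computes votes gene-by-gene over the adjacency dict and integrates the
    ROC by threshold sweep.
    """
    nodes = list(net.nodes)
    adj = net.adjacency()
    node_index = {g: i for i, g in enumerate(nodes)}
    members = sorted(node_index[g] for g in term_genes if g in node_index)
    rng = np.random.default_rng([seed, term_index])
    folds = np.array_split(rng.permutation(np.array(members, dtype=np.int64)), n_folds)
    fold_aurocs = []
    for fold in folds:
        train = set(members) - set(fold.tolist())
        train_genes = {nodes[i] for i in train}
        votes = {}
        for g in nodes:
            nbrs = adj[g]
            votes[g] = sum(1 for nb in nbrs if nb in train_genes) / len(nbrs)
        eval_genes = [g for g in nodes if g not in train_genes]
        pos = [votes[nodes[i]] for i in fold.tolist()]
        neg = [votes[g] for g in eval_genes if node_index[g] not in set(fold.tolist())]
        fold_aurocs.append(roc_integrate(pos, neg))
    return float(np.mean(fold_aurocs))


def bh_stepup(p_values) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = math.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p_values[i] * m / rank_from_top
        running_min = min(running_min, value, 1.0)
        adjusted[i] = running_min
    return adjusted


def topk_union_network_edges(hrr_matrix, gene_ids, k):
    """Exhaustive per-gene best-k union for a small HRR matrix.

    Partners sorted by (hrr, gene id); returns the canonical edge set.
    """
    g = len(gene_ids)
    edges = set()
    for i in range(g):
        partners = sorted(
            (j for j in range(g) if j != i),
            key=lambda j: (hrr_matrix[i][j], gene_ids[j]),
        )[:k]
        for j in partners:
            a, b = sorted((gene_ids[i], gene_ids[j]))
            edges.add((a, b))
    return edges


def coo_topk_edges(group_edge_sets_with_scores, gene_ids, k):
    """Exhaustive co-occurrence top-k union over group edge dicts."""
    freq: dict[tuple[str, str], int] = {}
    total: dict[tuple[str, str], float] = {}
    for edges in group_edge_sets_with_scores:
        for e, s in edges.items():
            freq[e] = freq.get(e, 0) + 1
            total[e] = total.get(e, 0.0) + s
    selected = set()
    for g in gene_ids:
        cands = [e for e in freq if g in e]
        cands.sort(
            key=lambda e: (
                -freq[e],
                total[e] / freq[e],
                e[1] if e[0] == g else e[0],
            )
        )
        selected.update(cands[:k])
    return {e: freq[e] for e in selected}


def random_small_network(rng, n_nodes):
    """Random network on n_nodes genes with no isolated node (for oracles)."""
    import gcnkit as gk

    nodes = tuple(f"g{i:02d}" for i in range(n_nodes))
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.4:
                edges[(nodes[i], nodes[j])] = 1
    degree = {g: 0 for g in nodes}
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    for g in nodes:
        if degree[g] == 0:
            partner = nodes[(nodes.index(g) + 1) % n_nodes]
            a, b = sorted((g, partner))
            edges[(a, b)] = 1
            degree[a] += 1
            degree[b] += 1
    return gk.Network(method="HRR", k=2, nodes=nodes, edges=edges)


def hypergeom_exact(overlap, universe, term, drawn) -> float:
    """Upper-tail hypergeometric probability by explicit summation."""
    total = 0.0
    for x in range(overlap, min(term, drawn) + 1):
        total += (
            math.comb(term, x)
            * math.comb(universe - term, drawn - x)
            / math.comb(universe, drawn)
        )
    return total
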