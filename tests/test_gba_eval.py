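import numpy as np
import pandas as pd
import pytest

import gcnkit as gk

import oracles
from oracles import random_small_network


class TestFilterTerms:
    def _ann(self, sizes, prefix="T"):
        terms = {
            f"{prefix}{i}": frozenset(f"g{i:02d}_{j:04d}" for j in range(size))
            for i, size in enumerate(sizes)
        }
        return gk.AnnotationCollection(dataset_name="ds", terms=terms)

    def _net_with(self, genes):
        nodes = tuple(sorted(genes))
        edges = {}
        for i in range(len(nodes) - 1):
            edges[tuple(sorted((nodes[i], nodes[i + 1])))] = 1
        return gk.Network(method="HRR", k=1, nodes=nodes, edges=edges)

    def test_boundaries_inclusive(self):
        ann = self._ann([19, 20, 50])
        genes = set().union(*ann.terms.values())
        net = self._net_with(genes)
        out = gk.filter_terms(ann, net, min_size=20, max_size=1000)
        assert sorted(out.terms) == ["T1", "T2"]

    def test_intersection_precedes_size_check(self):
        big = frozenset(f"x{j:04d}" for j in range(1500))
        in_net = set(list(big)[:900])
        ann = gk.AnnotationCollection(dataset_name="ds", terms={"BIG": big})
        net = self._net_with(in_net)
        out = gk.filter_terms(ann, net, min_size=20, max_size=1000)
        assert len(out.terms["BIG"]) == 900

    def test_no_survivor_errors(self):
        ann = self._ann([5, 8])
        net = self._net_with(set().union(*ann.terms.values()))
        with pytest.raises(ValueError, match="no term"):
            gk.filter_terms(ann, net, min_size=20)


class TestNeighborVoting:
    def test_planted_clique_term_is_perfect(self, gba_demo):
        net, ann = gba_demo
        table = gk.neighbor_voting_auroc(net, ann, n_folds=2, seed=0)
        assert table.loc[0, "auroc"] == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_small_networks(self):
        rng = np.random.default_rng(12)
        for trial in range(12):
            n_nodes = int(rng.integers(6, 11))
            net = random_small_network(rng, n_nodes)
            term_size = int(rng.integers(3, 6))
            term_genes = frozenset(
                rng.choice(net.nodes, size=term_size, replace=False).tolist()
            )
            ann = gk.AnnotationCollection(
                dataset_name="ds", terms={"T": term_genes}
            )
            table = gk.neighbor_voting_auroc(net, ann, n_folds=3, seed=trial)
            expected = oracles.neighbor_voting_oracle(
                net, term_genes, n_folds=3, seed=trial, term_index=0
            )
            assert table.loc[0, "auroc"] == pytest.approx(expected, abs=1e-12)

    def test_random_labels_score_near_half(self, small_network):
        rng = np.random.default_rng(77)
        terms = {
            f"R{i:03d}": frozenset(
                rng.choice(small_network.nodes, size=20, replace=False).tolist()
            )
            for i in range(60)
        }
        ann = gk.AnnotationCollection(dataset_name="null", terms=terms)
        table = gk.neighbor_voting_auroc(small_network, ann, n_folds=3, seed=5)
        assert table["auroc"].mean() == pytest.approx(0.5, abs=0.05)
        assert table["auroc"].between(0, 1).all()

    def test_auroc_invariant_to_relabeling_outside_term(self, gba_demo):
        net, ann = gba_demo
        before = gk.neighbor_voting_auroc(net, ann, n_folds=2, seed=3)
        renamed = {g: (g if g in ann.terms["T_CLIQUE"] else g.replace("n", "z"))
                   for g in net.nodes}
        net2 = gk.Network(
            method=net.method, k=net.k,
            nodes=tuple(renamed[g] for g in net.nodes),
            edges={tuple(sorted((renamed[a], renamed[b]))): s
                   for (a, b), s in net.edges.items()},
        )
        after = gk.neighbor_voting_auroc(net2, ann, n_folds=2, seed=3)
        assert after.loc[0, "auroc"] == pytest.approx(before.loc[0, "auroc"])

    def test_term_smaller_than_folds_skipped(self, gba_demo):
        net, _ = gba_demo
        ann = gk.AnnotationCollection(
            dataset_name="ds", terms={"TINY": frozenset(["n1", "n2"])}
        )
        table = gk.neighbor_voting_auroc(net, ann, n_folds=3, seed=0)
        assert table.empty

    def test_determinism(self, small_network):
        rng = np.random.default_rng(3)
        terms = {
            f"R{i}": frozenset(
                rng.choice(small_network.nodes, size=15, replace=False).tolist()
            )
            for i in range(5)
        }
        ann = gk.AnnotationCollection(dataset_name="ds", terms=terms)
        t1 = gk.neighbor_voting_auroc(small_network, ann, n_folds=3, seed=9)
        t2 = gk.neighbor_voting_auroc(small_network, ann, n_folds=3, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestRocAuc:
    @pytest.mark.parametrize("seed", range(6))
    def test_rank_sum_equals_integration_and_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(0, 1, size=30), 2)  # force ties
        positive = np.zeros(30, dtype=bool)
        positive[rng.choice(30, size=8, replace=False)] = True
        ours = gk.roc_auc_from_scores(scores, positive)
        pos, neg = scores[positive].tolist(), scores[~positive].tolist()
        assert ours == pytest.approx(oracles.roc_integrate(pos, neg), abs=1e-12)
        assert ours == pytest.approx(oracles.pairwise_auroc(pos, neg), abs=1e-12)


class TestDatasetMeans:
    def _rows(self, spec):
        return pd.DataFrame(
            [
                {"dataset_name": ds, "term_id": f"t{i}", "n_genes": 25,
                 "auroc": a, "mean_degree": 4.0}
                for i, (ds, a) in enumerate(spec)
            ]
        )

    def test_single_term(self):
        per_ds, grand = gk.dataset_mean_auroc(self._rows([("d1", 0.8)]))
        assert per_ds["d1"] == pytest.approx(0.8)
        assert grand == pytest.approx(0.8)

    def test_grand_mean_across_datasets(self):
        per_ds, grand = gk.dataset_mean_auroc(
            self._rows([("d1", 0.6), ("d1", 0.8), ("d2", 0.9)])
        )
        assert per_ds["d1"] == pytest.approx(0.7)
        assert grand == pytest.approx(0.8)

    def test_permutation_invariant(self):
        rows = self._rows([("d1", 0.6), ("d2", 0.9), ("d1", 0.7)])
        _, g1 = gk.dataset_mean_auroc(rows)
        _, g2 = gk.dataset_mean_auroc(rows.iloc[::-1].reset_index(drop=True))
        assert g1 == pytest.approx(g2)

    def test_term_degree_table_is_passthrough(self, gba_demo):
        net, ann = gba_demo
        rows = gk.neighbor_voting_auroc(net, ann, n_folds=2, seed=0)
        table = gk.term_degree_table(rows)
        assert len(table) == len(rows)
        # hand count: clique members have degrees 3,4,3,4 -> mean 3.5
        assert table.loc[0, "mean_degree"] == pytest.approx(3.5)


@pytest.fixture(scope="module")
def grouped():
    cfg = gk.SyntheticConfig(
        n_genes=150, n_groups=4, samples_per_group=6, n_modules=3,
        module_size=22, within_module_correlation=0.85, seed=31,
    )
    cm, st_, ann, _ = gk.simulate_dataset(cfg)
    return gk.group_by_bioproject(cm, st_, min_libraries=6), ann


class TestSubsetCurve:
    def test_row_count(self, grouped):
        ge, ann = grouped
        table = gk.bioproject_subset_curve(
            ge, ann, methods=["HRR", "COO"], k_values=[10], sizes=[2, 3, 4],
            n_replicates=5, seed=2, min_term_size=15,
        )
        assert len(table) == 3 * 5 * 2  # sizes x replicates x methods (1 k, 1 dataset)
        assert set(table["method"]) == {"HRR", "COO"}
        assert table["replicate"].between(1, 5).all()

    def test_same_seed_reproduces_table(self, grouped):
        ge, ann = grouped
        kwargs = dict(methods=["COO"], k_values=[10], sizes=[2, 4],
                      n_replicates=2, seed=11, min_term_size=15)
        t1 = gk.bioproject_subset_curve(ge, ann, **kwargs)
        t2 = gk.bioproject_subset_curve(ge, ann, **kwargs)
        pd.testing.assert_frame_equal(t1, t2)

    def test_oversized_subset_rejected(self, grouped):
        ge, ann = grouped
        with pytest.raises(ValueError, match="sizes"):
            gk.bioproject_subset_curve(ge, ann, sizes=[2, 9], k_values=[10])
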