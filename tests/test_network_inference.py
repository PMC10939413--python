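import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gcnkit as gk
from gcnkit.network_inference import canonical_edge

import oracles


def _fm(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or tuple(f"g{i}" for i in range(values.shape[0]))
    return gk.FpkmMatrix(
        gene_ids=genes,
        sample_ids=tuple(f"s{j}" for j in range(values.shape[1])),
        fpkm=values,
    )


class TestPccRank:
    def test_identical_genes_rank_each_other_first(self):
        base = np.array([1.0, 2.0, 5.0, 3.0, 8.0])
        fm = _fm([base, base, base[::-1], base + np.array([0, 1, 0, 2, 0])])
        rs = gk.pcc_rank(fm)
        assert rs.pcc[0, 1] == pytest.approx(1.0)
        assert rs.rank("g0", "g1") == 1
        assert rs.rank("g1", "g0") == 1

    def test_ranks_follow_descending_pcc(self, hrr_demo):
        rs = gk.pcc_rank(hrr_demo)
        g = len(rs.gene_ids)
        for i in range(g):
            # brute-force re-sort of the partner list
            partners = sorted(
                (j for j in range(g) if j != i),
                key=lambda j: (-rs.pcc[i, j], rs.gene_ids[j]),
            )
            expected = {rs.gene_ids[j]: pos + 1 for pos, j in enumerate(partners)}
            for j in range(g):
                if j != i:
                    assert rs.ranks[i, j] == expected[rs.gene_ids[j]]

    def test_rank_rows_are_permutations(self, hrr_demo):
        rs = gk.pcc_rank(hrr_demo)
        g = len(rs.gene_ids)
        for i in range(g):
            row = np.delete(rs.ranks[i], i)
            assert sorted(row.tolist()) == list(range(1, g))

    def test_zero_variance_gene_rejected(self):
        fm = _fm([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            gk.pcc_rank(fm)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            gk.pcc_rank(_fm([[1.0, 2.0], [2.0, 1.0]]))


class TestHrrScores:
    def test_max_of_asymmetric_ranks(self):
        ranks = np.array([[0, 3], [7, 0]], dtype=np.int32)
        rs = gk.RankStructure(
            gene_ids=("x", "y"), pcc=np.eye(2), ranks=ranks
        )
        hm = gk.hrr_scores(rs)
        assert hm.value("x", "y") == 7 == hm.value("y", "x")

    def test_symmetry_on_random_fixture(self, hrr_demo):
        hm = gk.hrr_scores(gk.pcc_rank(hrr_demo))
        np.testing.assert_array_equal(hm.hrr, hm.hrr.T)
        assert (np.diag(hm.hrr) == 0).all()
        assert (hm.hrr >= np.triu(gk.pcc_rank(hrr_demo).ranks, 1)).all()


class TestHrrNetwork:
    def test_small_complete_graph_when_k_exceeds_genes(self):
        fm = _fm(np.random.default_rng(3).uniform(1, 5, size=(4, 6)))
        hm = gk.hrr_scores(gk.pcc_rank(fm))
        with pytest.warns(UserWarning, match="complete graph"):
            net = gk.build_hrr_network(hm, 5)
        assert net.n_edges == 6
        assert set(net.degrees().values()) == {3}

    def test_edge_set_matches_bruteforce_union(self, hrr_demo):
        hm = gk.hrr_scores(gk.pcc_rank(hrr_demo))
        net = gk.build_hrr_network(hm, 2)
        expected = oracles.topk_union_network_edges(
            hm.hrr.tolist(), list(hm.gene_ids), 2
        )
        assert set(net.edges) == expected

    def test_edge_scores_are_hrr_values(self, hrr_demo):
        hm = gk.hrr_scores(gk.pcc_rank(hrr_demo))
        net = gk.build_hrr_network(hm, 2)
        for (a, b), score in net.edges.items():
            assert score == hm.value(a, b)

    def test_degree_floor(self, small_network):
        degrees = small_network.degrees().values()
        assert min(degrees) == small_network.k

    def test_monotone_in_k(self, hrr_demo):
        hm = gk.hrr_scores(gk.pcc_rank(hrr_demo))
        edges2 = set(gk.build_hrr_network(hm, 2).edges)
        edges4 = set(gk.build_hrr_network(hm, 4).edges)
        assert edges2 <= edges4

    def test_strict_mutual_is_subset(self, hrr_demo):
        hm = gk.hrr_scores(gk.pcc_rank(hrr_demo))
        strict = gk.build_hrr_network(hm, 2, strict_mutual=True)
        union = gk.build_hrr_network(hm, 2)
        assert set(strict.edges) <= set(union.edges)
        assert all(s <= 2 for s in strict.edges.values())

    def test_invariance_to_sample_permutation_and_scaling(self, hrr_demo):
        net = gk.hrr_network_from_fpkm(hrr_demo, 2)
        perm = np.random.default_rng(1).permutation(len(hrr_demo.sample_ids))
        shuffled = gk.FpkmMatrix(
            gene_ids=hrr_demo.gene_ids,
            sample_ids=tuple(hrr_demo.sample_ids[i] for i in perm),
            fpkm=hrr_demo.fpkm[:, perm] * 3.5,
        )
        net2 = gk.hrr_network_from_fpkm(shuffled, 2)
        assert set(net.edges) == set(net2.edges)


class TestCooNetwork:
    def _group_nets(self, n_groups, n_genes=10, k=2, seed=0):
        rng = np.random.default_rng(seed)
        nets = []
        for _ in range(n_groups):
            fm = _fm(rng.uniform(1, 9, size=(n_genes, 8)))
            nets.append(gk.hrr_network_from_fpkm(fm, k))
        return nets

    def test_frequency_counts_group_membership(self):
        nets = self._group_nets(5)
        coo = gk.build_coo_network(nets, 2)
        for edge, freq in coo.edges.items():
            assert freq == sum(edge in n.edges for n in nets)
            assert 1 <= freq <= 5
        assert coo.n_groups == 5

    def test_identical_groups_reduce_to_shared_topk(self):
        rng = np.random.default_rng(8)
        fm = _fm(rng.uniform(1, 9, size=(10, 8)))
        net = gk.hrr_network_from_fpkm(fm, 2)
        coo = gk.build_coo_network([net, net], 2)
        expected = oracles.coo_topk_edges(
            [dict(net.edges), dict(net.edges)], sorted(net.nodes), 2
        )
        assert coo.edges == expected
        assert set(coo.edges) == set(net.edges)
        assert all(f == 2 for f in coo.edges.values())

    def test_matches_exhaustive_aggregation_oracle(self):
        nets = self._group_nets(3, n_genes=9, k=2, seed=4)
        coo = gk.build_coo_network(nets, 2)
        expected = oracles.coo_topk_edges(
            [dict(n.edges) for n in nets],
            sorted(set().union(*(n.nodes for n in nets))),
            2,
        )
        assert coo.edges == expected

    def test_group_specific_gene_kept_in_union(self):
        nets = self._group_nets(2, n_genes=8, seed=2)
        extra_nodes = nets[0].nodes + ("zz_only",)
        edges = dict(nets[0].edges)
        edges[canonical_edge("zz_only", nets[0].nodes[0])] = 1
        bigger = gk.Network(method="HRR", k=2, nodes=extra_nodes, edges=edges)
        coo = gk.build_coo_network([bigger, nets[1]], 2)
        assert "zz_only" in coo.nodes

    def test_mismatched_k_rejected(self):
        nets = self._group_nets(2, k=2)
        other = self._group_nets(1, k=3, seed=9)[0]
        with pytest.raises(ValueError, match="k="):
            gk.build_coo_network([nets[0], other], 2)

    def test_degree_floor_holds(self):
        nets = self._group_nets(4, n_genes=12, k=3, seed=6)
        coo = gk.build_coo_network(nets, 3)
        assert min(coo.degrees().values()) >= 3


class TestNetworkContainer:
    @given(seed=st.integers(0, 500))
    def test_handshake_lemma(self, seed):
        rng = np.random.default_rng(seed)
        fm = _fm(rng.uniform(1, 9, size=(8, 6)))
        net = gk.hrr_network_from_fpkm(fm, 2)
        assert sum(net.degrees().values()) == 2 * net.n_edges

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            gk.Network(method="HRR", k=1, nodes=("a",), edges={("a", "a"): 1})
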