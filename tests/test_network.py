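import numpy as np
import pandas as pd
import pytest

from coexnet import (
    NetworkParams,
    build_network,
    degree_distribution,
    pcc,
    pcc_matrix,
    rank_neighbors,
    select_edges,
)

from conftest import make_matrix
from _reference import naive_edges, naive_mr, naive_pcc_matrix, naive_ranks


def random_store(n_genes=50, n_samples=8, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.gamma(2.0, 10.0, size=(n_genes, n_samples))
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    df = pd.DataFrame(vals, index=gene_ids, columns=[f"s{j}" for j in range(n_samples)])
    return df, pcc_matrix(df)


class TestPcc:
    @pytest.mark.parametrize(
        "x, y, expect",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (6, 4, 2), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # covariance 4, variances 5 each
        ],
    )
    def test_known_values(self, x, y, expect):
        assert pcc(x, y) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(pcc((1, 1, 1), (1, 2, 3)))

    def test_length_checks(self):
        with pytest.raises(ValueError):
            pcc((1, 2), (1, 2, 3))
        with pytest.raises(ValueError):
            pcc((1,), (2,))


class TestPccMatrix:
    def test_matches_pairwise_oracle(self):
        df, store = random_store(n_genes=40, seed=3)
        expect = naive_pcc_matrix(df.to_numpy())
        np.testing.assert_allclose(store.pcc, expect, atol=1e-12)

    def test_symmetry_and_bounds(self):
        _, store = random_store(seed=4)
        np.testing.assert_array_equal(store.pcc, store.pcc.T)
        assert np.nanmax(np.abs(store.pcc)) <= 1.0 + 1e-12

    def test_constant_gene_masked_others_unaffected(self):
        df, _ = random_store(n_genes=10, seed=5)
        df.iloc[3] = 7.0
        store = pcc_matrix(df)
        assert store.undefined[3]
        assert np.isnan(store.pcc[3]).all()
        clean = pcc_matrix(df.drop(index=df.index[3]))
        others = [i for i in range(10) if i != 3]
        np.testing.assert_allclose(store.pcc[np.ix_(others, others)], clean.pcc, atol=0)

    def test_too_few_genes_rejected(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            pcc_matrix(df)


class TestRankNeighbors:
    def test_simple_rank_order(self):
        # gene a's |pcc| to (b, c, d) = (0.9, 0.5, 0.7) -> ranks 1, 3, 2
        ids = ["a", "b", "c", "d"]
        p = np.array(
            [
                [1.0, 0.9, 0.5, -0.7],
                [0.9, 1.0, 0.2, 0.1],
                [0.5, 0.2, 1.0, 0.3],
                [-0.7, 0.1, 0.3, 1.0],
            ]
        )
        from coexnet.network import CorrelationStore

        store = CorrelationStore(gene_ids=ids, pcc=p, undefined=np.zeros(4, bool))
        r = rank_neighbors(store)
        a = ids.index("a")
        assert r.rank[a, ids.index("b")] == 1
        assert r.rank[a, ids.index("d")] == 2
        assert r.rank[a, ids.index("c")] == 3

    def test_mutual_rank_geometric_mean(self):
        _, store = random_store(seed=6)
        r = rank_neighbors(store)
        n = len(store.gene_ids)
        iu = np.triu_indices(n, 1)
        np.testing.assert_allclose(
            r.mr[iu], np.sqrt(r.rank[iu] * r.rank.T[iu]), atol=1e-9
        )
        assert np.nanmin(r.mr[iu]) >= 1.0

    def test_rows_are_permutations(self):
        _, store = random_store(seed=7)
        r = rank_neighbors(store)
        n = len(store.gene_ids)
        for a in range(n):
            row = np.delete(r.rank[a], a)
            assert sorted(row) == list(range(1, n))

    def test_matches_naive_ranks_with_tie_break(self):
        df, store = random_store(n_genes=30, seed=8)
        r = rank_neighbors(store)
        expect = naive_ranks(store.pcc, store.gene_ids)
        np.testing.assert_array_equal(r.rank, expect)
        np.testing.assert_allclose(r.mr, naive_mr(expect), equal_nan=True)

    def test_ties_broken_by_ascending_gene_id(self):
        # b and c tie at |pcc| = 1 from a's viewpoint
        vals = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]]
        df = pd.DataFrame(vals, index=["a", "c", "b"], columns=["s1", "s2", "s3"])
        r = rank_neighbors(pcc_matrix(df))
        assert r.rank[0, 2] == 1  # 'b' before 'c'
        assert r.rank[0, 1] == 2


class TestSelectEdges:
    def test_matches_brute_force_enumeration(self):
        _, store = random_store(n_genes=50, seed=9)
        params = NetworkParams(pcc_cutoff=0.5, top_k=3, mr_cutoff=10)
        r = rank_neighbors(store)
        net = select_edges(store, r, params)
        got = {tuple(sorted(e)) for e in net.graph.edges}
        expect = naive_edges(
            store.pcc, r.rank, r.mr, store.gene_ids, pcc_cutoff=0.5, top_k=3, mr_cutoff=10
        )
        assert got == expect

    def test_pcc_cutoff_is_conjunct(self):
        _, store = random_store(seed=10)
        r = rank_neighbors(store)
        net = select_edges(store, r, NetworkParams(pcc_cutoff=0.8, top_k=3, mr_cutoff=30))
        for u, v, d in net.graph.edges(data=True):
            assert abs(d["pcc"]) >= 0.8

    def test_sign_assignment_and_counts(self):
        _, store = random_store(seed=11)
        r = rank_neighbors(store)
        net = select_edges(store, r, NetworkParams(pcc_cutoff=0.3, mr_cutoff=20))
        counts = net.edge_count_by_sign()
        assert counts["positive"] + counts["negative"] == net.graph.number_of_edges()
        for _, _, d in net.graph.edges(data=True):
            assert d["sign"] == ("positive" if d["pcc"] > 0 else "negative")

    @pytest.mark.parametrize("tighten", ["mr", "pcc"])
    def test_threshold_monotonicity(self, tighten):
        _, store = random_store(seed=12)
        r = rank_neighbors(store)
        loose = NetworkParams(pcc_cutoff=0.5, top_k=2, mr_cutoff=30)
        tight = (
            NetworkParams(pcc_cutoff=0.5, top_k=2, mr_cutoff=10)
            if tighten == "mr"
            else NetworkParams(pcc_cutoff=0.8, top_k=2, mr_cutoff=30)
        )
        e_loose = set(select_edges(store, r, loose).graph.edges)
        e_tight = set(select_edges(store, r, tight).graph.edges)
        assert e_tight <= e_loose

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(pcc_cutoff=1.5)
        with pytest.raises(ValueError):
            NetworkParams(mr_cutoff=0.5)


class TestBuildNetwork:
    def test_zero_noise_modules_fully_connected_with_signs(self, zero_noise_sim):
        m, truth = zero_noise_sim
        net, _ = build_network(m)
        for module, members in truth.planted_gene_sets.items():
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    assert net.graph.has_edge(a, b), (module, a, b)
                    same = truth.sign_of_gene[a] == truth.sign_of_gene[b]
                    assert net.graph.edges[a, b]["sign"] == (
                        "positive" if same else "negative"
                    )

    def test_silent_genes_dropped(self, small_sim):
        m, truth = small_sim
        net, _ = build_network(m)
        silent = {g for g, mod in truth.module_of_gene.items() if mod == "silent"}
        assert silent <= set(net.dropped_genes)
        assert not silent & set(net.nodes)

    def test_edge_table_canonical_order(self, small_sim):
        m, _ = small_sim
        net, _ = build_network(m)
        t = net.edge_table()
        assert (t["gene_a"] < t["gene_b"]).all()
        assert t.equals(t.sort_values(["gene_a", "gene_b"], ignore_index=True))


class TestDegreeDistribution:
    def test_star_graph_histogram(self):
        import networkx as nx
        from coexnet.network import CoexpressionNetwork

        g = nx.star_graph(5)  # hub + 5 leaves
        for u, v in g.edges:
            g.edges[u, v].update(pcc=0.9, mr=1.0, sign="positive")
        net = CoexpressionNetwork(graph=g, params=NetworkParams())
        stats = degree_distribution(net)
        assert stats.histogram.to_dict() == {1: 5, 5: 1}
        assert stats.n_isolated == 0

    def test_histogram_conserves_nodes(self, small_sim):
        m, _ = small_sim
        net, _ = build_network(m)
        stats = degree_distribution(net)
        assert stats.histogram.sum() + stats.n_isolated == len(net.nodes)

    def test_modular_network_slope_negative(self):
        # hub-and-spoke-ish modular structure: many degree-1 nodes, few hubs
        import networkx as nx
        from coexnet.network import CoexpressionNetwork

        g = nx.Graph()
        for h in range(4):
            for leaf in range(12):
                g.add_edge(f"hub{h}", f"leaf{h}_{leaf}", pcc=0.9, mr=2.0, sign="positive")
        net = CoexpressionNetwork(graph=g, params=NetworkParams())
        stats = degree_distribution(net)
        assert stats.slope < 0

    def test_empty_network_rejected(self):
        import networkx as nx
        from coexnet.network import CoexpressionNetwork

        net = CoexpressionNetwork(graph=nx.empty_graph(3), params=NetworkParams())
        with pytest.raises(ValueError):
            degree_distribution(net)
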