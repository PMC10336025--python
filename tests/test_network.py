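"""Network construction, clustering, graph summaries, ER null, bootstrap."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import copulacov as cc
from copulacov.network import (CovariationNetwork, CovariationNetworkResult,
                               dice_coefficient, enumerate_pairs,
                               overlap_coefficient)


def _result_from_graph(G: nx.Graph, labels=None) -> CovariationNetworkResult:
    taxa = sorted(G.nodes())
    m = len(taxa)
    empty = pd.DataFrame(np.zeros((m, m)), index=taxa, columns=taxa)
    res = CovariationNetworkResult(
        taxa=taxa, theta_matrix=empty, pvalue_matrix=empty.copy(),
        padj_matrix=empty.copy(),
        adjacency=pd.DataFrame(nx.to_numpy_array(G, nodelist=taxa) > 0,
                               index=taxa, columns=taxa),
        edges=pd.DataFrame(columns=["taxon_a", "taxon_b", "theta", "lambda",
                                    "p_raw", "at_boundary", "p_adj", "significant"]),
        q=0.01, failures=pd.DataFrame(columns=["taxon_a", "taxon_b", "reason"]),
        graph=G,
    )
    if labels is not None:
        res.cluster_labels = pd.Series(labels, index=taxa)
    return res


@pytest.fixture(scope="module")
def block_table():
    """Two blocks of strongly covarying taxa, independent across blocks."""
    pairs = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
    table, truth = cc.sample_multivariate_table(
        n_taxa=6, n_samples=250, dependency_graph=pairs,
        latent_correlation=0.9, seed=5, p_range=(0.1, 0.3),
    )
    return table, truth


@pytest.fixture(scope="module")
def block_result(block_table):
    table, _ = block_table
    res = cc.pairwise_analysis(table, q=0.05)
    cc.cluster_network(res, n_clusters=2)
    return res


def test_pair_enumeration_counts():
    assert len(enumerate_pairs(["a", "b", "c"])) == 3
    assert len(enumerate_pairs([str(i) for i in range(68)])) == 2278


def test_edge_set_is_exactly_the_by_rejection_set(block_result):
    reject, _ = cc.by_fdr(block_result.edges["p_raw"].to_numpy(), block_result.q)
    np.testing.assert_array_equal(reject, block_result.edges["significant"].to_numpy())
    assert len(block_result.edge_set) == int(reject.sum())


def test_true_pairs_all_detected(block_table, block_result):
    _, truth = block_table
    truth_set = {tuple(sorted(t)) for t in zip(truth.taxon_a, truth.taxon_b)}
    assert truth_set <= block_result.edge_set
    # within-block dependence is estimated positive and strong
    for a, b in truth_set:
        assert block_result.theta_matrix.loc[a, b] > 2.0


def _result_from_theta(W: np.ndarray) -> CovariationNetworkResult:
    taxa = [f"t{i}" for i in range(W.shape[0])]
    theta = pd.DataFrame(W, index=taxa, columns=taxa)
    adj = pd.DataFrame(W != 0, index=taxa, columns=taxa)
    G = nx.from_pandas_adjacency(adj.astype(int))
    return CovariationNetworkResult(
        taxa=taxa, theta_matrix=theta, pvalue_matrix=theta * np.nan,
        padj_matrix=theta * np.nan, adjacency=adj,
        edges=pd.DataFrame(columns=["taxon_a", "taxon_b", "theta", "lambda",
                                    "p_raw", "at_boundary", "p_adj", "significant"]),
        q=0.01, failures=pd.DataFrame(columns=["taxon_a", "taxon_b", "reason"]),
        graph=G,
    )


def test_block_theta_matrix_clusters_recover_blocks():
    # two perfectly separated blocks of positive theta
    W = np.zeros((6, 6))
    for block in ((0, 1, 2), (3, 4, 5)):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 3.0
    res = cc.cluster_network(_result_from_theta(W), n_clusters=2)
    labels = res.cluster_labels
    assert len({labels[f"t{i}"] for i in (0, 1, 2)}) == 1
    assert len({labels[f"t{i}"] for i in (3, 4, 5)}) == 1
    assert labels["t0"] != labels["t3"]


def test_column_permutation_equivariance(block_table):
    table, _ = block_table
    res = cc.pairwise_analysis(table, q=0.05)
    perm = list(table.columns[::-1])
    res_p = cc.pairwise_analysis(table[perm], q=0.05)
    pd.testing.assert_frame_equal(
        res.theta_matrix.loc[perm, perm], res_p.theta_matrix, atol=1e-9
    )
    assert res.edge_set == res_p.edge_set


def test_weighted_adjacency_zeroes_nonsignificant(block_result):
    W = block_result.weighted_adjacency()
    nonsig = ~block_result.adjacency.to_numpy()
    assert (W.to_numpy()[nonsig] == 0.0).all()


def test_too_few_taxa_raises():
    with pytest.raises(ValueError):
        cc.pairwise_analysis(pd.DataFrame(np.random.rand(10, 2)))


class TestGraphSummaries:
    def test_complete_graph(self):
        res = _result_from_graph(nx.complete_graph(4))
        s = cc.graph_summaries(res)
        assert np.allclose(s["per_node"]["degree"], 1.0)
        assert s["density"] == 1.0
        assert s["diameter"] == 1

    def test_path_graph_hand_computation(self):
        res = _result_from_graph(nx.path_graph(4))
        s = cc.graph_summaries(res)
        # path 0-1-2-3: closeness(0) = 3/(1+2+3); betweenness(1) = 2 of 3 pairs
        assert s["per_node"].loc[0, "closeness"] == pytest.approx(0.5)
        assert s["per_node"].loc[1, "betweenness"] == pytest.approx(2 / 3)
        assert s["diameter"] == 3
        assert s["mean_distance"] == pytest.approx((1 * 3 + 2 * 2 + 3) / 6)

    def test_empty_graph_flagged(self):
        G = nx.empty_graph(5)
        s = cc.graph_summaries(_result_from_graph(G))
        assert s["density"] == 0.0
        assert s["diameter"] is None
        assert s["largest_component_only"]

    def test_modularity_of_provided_partition(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        res = _result_from_graph(G, labels=[1, 1, 1, 2, 2, 2])
        s = cc.graph_summaries(res)
        expected = nx.algorithms.community.modularity(G, [{0, 1, 2}, {3, 4, 5}])
        assert s["modularity"] == pytest.approx(expected)


class TestClustering:
    def test_degenerate_all_equal_dissimilarity_warns(self):
        res = _result_from_graph(nx.empty_graph(4))
        with pytest.warns(UserWarning, match="single cluster"):
            cc.cluster_network(res, n_clusters=2)

    def test_assignment_invariant_to_taxon_order(self, block_table):
        table, _ = block_table
        r1 = cc.cluster_network(cc.pairwise_analysis(table, q=0.05), 2)
        perm = list(table.columns[::-1])
        r2 = cc.cluster_network(cc.pairwise_analysis(table[perm], q=0.05), 2)
        l1 = r1.cluster_labels
        l2 = r2.cluster_labels
        # same partition up to label renaming
        groups1 = {t: frozenset(l1.index[l1 == l1[t]]) for t in l1.index}
        groups2 = {t: frozenset(l2.index[l2 == l2[t]]) for t in l2.index}
        assert groups1 == groups2


class TestErdosRenyiNull:
    def test_seeded_determinism(self, block_result):
        a = cc.er_null_comparison(block_result, n_graphs=50, seed=1)
        b = cc.er_null_comparison(block_result, n_graphs=50, seed=1)
        np.testing.assert_array_equal(a["null_clustering"], b["null_clustering"])
        assert a["p_modularity"] == b["p_modularity"]

    def test_null_clustering_approximates_density(self):
        rng = np.random.default_rng(2)
        G = nx.gnm_random_graph(40, 180, seed=7)
        res = _result_from_graph(G)
        out = cc.er_null_comparison(res, n_graphs=100, seed=3)
        assert out["null_clustering"].mean() == pytest.approx(nx.density(G), abs=0.02)

    def test_clustered_network_beats_null_modularity(self):
        # two dense 6-cliques joined by one bridge: genuinely modular
        G = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        G.add_edge(0, 6)
        res = _result_from_graph(G, labels=[1] * 6 + [2] * 6)
        out = cc.er_null_comparison(res, n_graphs=200, seed=11, n_clusters=2)
        assert out["observed_modularity"] >= np.quantile(out["null_modularity"], 0.99)
        assert out["p_modularity"] <= 0.01

    def test_self_calibration_under_the_null(self):
        # an observed graph drawn from G(m, M) should not look extreme
        pvals = []
        for seed in range(25):
            G = nx.gnm_random_graph(12, 18, seed=seed)
            res = _result_from_graph(G)
            out = cc.er_null_comparison(res, n_graphs=100, seed=seed + 1000)
            pvals.append(out["p_clustering"])
        pvals = np.array(pvals)
        assert (pvals < 0.05).mean() <= 0.25
        assert pvals.mean() > 0.25


class TestBootstrap:
    def test_overlap_and_dice_arithmetic(self):
        A = {("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")}
        B = A - {("c", "d")} | {("d", "e"), ("a", "d")}
        assert len(A) == 4 and len(B) == 5 and len(A & B) == 3
        assert overlap_coefficient(A, B) == pytest.approx(0.75)
        assert dice_coefficient(A, B) == pytest.approx(2 * 3 / 9)
        assert overlap_coefficient(A, A) == dice_coefficient(A, A) == 1.0
        assert overlap_coefficient(A, {("x", "y")}) == 0.0
        assert dice_coefficient(set(), set()) == 0.0

    def test_bootstrap_summaries(self, block_table):
        table, _ = block_table
        out = cc.bootstrap_consistency(table, q=0.05, n_boot=5, seed=4)
        assert out["n_completed"] + out["n_skipped"] == 5
        assert 0.0 <= out["overlap_mean"] <= 1.0
        assert 0.0 <= out["dice_mean"] <= 1.0
        f = out["selection_frequency"]["selection_frequency"]
        assert ((f > 0) & (f <= 1.0)).all()
        # strong block edges should be highly reproducible
        assert out["overlap_mean"] > 0.5


class TestNetworkEstimator:
    def test_sklearn_contract_and_attributes(self, block_table):
        table, _ = block_table
        est = CovariationNetwork(q=0.05, n_clusters=2)
        assert clone(est).get_params() == est.get_params()
        labels = est.fit_predict(table)
        assert labels.shape == (6,)
        assert est.adjacency_.to_numpy().sum() > 0
        assert est.summaries_["density"] > 0
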