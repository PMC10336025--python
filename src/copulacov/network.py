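"""Covariation-network construction from all-pairs copula dependence tests.

Every unordered taxon pair is fitted with the two-stage Frank-copula model
and tested for independence with the likelihood-ratio test; the
Benjamini-Yekutieli procedure controls the FDR across all tested pairs.
Taxa are nodes; an edge joins two taxa whose test survives FDR, weighted by
the estimated dependence parameter theta. The module also provides
complete-linkage clustering of the weighted adjacency, standard graph
summaries, an Erdos-Renyi null ensemble for the global statistics, and a
row-bootstrap consistency analysis of the edge set.

Margins are fitted once per taxon and shared across that taxon's pairs —
stage 1 of the two-stage estimator depends only on the margin itself, so
this is exact, not an approximation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError, InsufficientDataError
from .estimation import optimize_theta
from .frank import THETA_MAX
from .inference import by_fdr, lrt_from_pairfit
from .joint import PairWorkspace
from .margins import MarginModel, fit_margin

__all__ = [
    "CovariationNetworkResult",
    "CovariationNetwork",
    "pairwise_analysis",
    "cluster_network",
    "graph_summaries",
    "er_null_comparison",
    "bootstrap_consistency",
    "overlap_coefficient",
    "dice_coefficient",
    "enumerate_pairs",
]


def enumerate_pairs(taxa: Sequence[str]) -> list[tuple[str, str]]:
    """All m*(m-1)/2 unordered taxon pairs, in label order."""
    return list(itertools.combinations(taxa, 2))


@dataclass
class CovariationNetworkResult:
    """All-pairs analysis output: matrices, edge calls, and the graph."""

    taxa: list
    theta_matrix: pd.DataFrame          # symmetric theta~ estimates, 0 diagonal
    pvalue_matrix: pd.DataFrame         # raw LRT p-values
    padj_matrix: pd.DataFrame           # BY-adjusted p-values
    adjacency: pd.DataFrame             # boolean edges at FDR q
    edges: pd.DataFrame                 # tidy per-pair records
    q: float
    failures: pd.DataFrame              # pairs skipped with a reason code
    cluster_labels: Optional[pd.Series] = None
    leaf_order: Optional[list] = None
    graph: Optional[nx.Graph] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def edge_set(self) -> set:
        sig = self.edges[self.edges["significant"]]
        return {tuple(sorted((a, b))) for a, b in zip(sig["taxon_a"], sig["taxon_b"])}

    def weighted_adjacency(self) -> pd.DataFrame:
        """theta~ weights on significant pairs, zero elsewhere (heatmap convention)."""
        return self.theta_matrix.where(self.adjacency, 0.0)


def _build_covariate_models(covariates: Optional[pd.DataFrame], n: int,
                            parts: tuple = ("p", "mu")) -> Optional[MarginModel]:
    """One shared MarginModel from a covariate DataFrame (intercept prepended)."""
    if covariates is None:
        return None
    Z = np.column_stack([np.ones(n), np.asarray(covariates, float)])
    return MarginModel(
        design_p=Z if "p" in parts else None,
        design_mu=Z if "mu" in parts else None,
        design_phi=Z if "phi" in parts else None,
    )


def pairwise_analysis(table: pd.DataFrame, covariates: Optional[pd.DataFrame] = None,
                      q: float = 0.01, *, theta_bound: float = THETA_MAX,
                      covariate_parts: tuple = ("p", "mu")) -> CovariationNetworkResult:
    """Two-stage fit + independence LRT on every unordered taxon pair, with BY FDR.

    Pairs violating estimability preconditions are recorded with a reason
    code and excluded from FDR (they contribute no test).
    """
    table = pd.DataFrame(table)
    taxa = list(table.columns)
    if len(taxa) < 3:
        raise ValueError("pairwise analysis needs at least 3 taxa")
    n = table.shape[0]
    from .margins import _ONE_MINUS, clean_abundances

    n_clamped = int((table.to_numpy(dtype=float) >= _ONE_MINUS).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # recorded in diagnostics instead
        X = clean_abundances(table.to_numpy(dtype=float), "abundance table")
    model = _build_covariate_models(covariates, n, covariate_parts)

    margin_fits = {}
    margin_fail = {}
    for t, name in enumerate(taxa):
        try:
            margin_fits[name] = fit_margin(X[:, t], model)
        except (InsufficientDataError, ValueError) as exc:
            margin_fail[name] = str(exc)

    records, failures = [], []
    for a, b in enumerate_pairs(taxa):
        if a in margin_fail or b in margin_fail:
            failures.append((a, b, "margin: " + margin_fail.get(a, margin_fail.get(b, ""))))
            continue
        xi = X[:, taxa.index(a)]
        xj = X[:, taxa.index(b)]
        joint = int(((xi > 0) & (xj > 0)).sum())
        if joint < 2:
            failures.append((a, b, f"jointly nonzero count {joint} < 2"))
            continue
        try:
            ws = PairWorkspace.build(xi, xj, margin_fits[a], margin_fits[b])
        except DegenerateDataError as exc:
            failures.append((a, b, str(exc)))
            continue
        theta, ll_max = optimize_theta(ws, theta_bound)
        ll_null = ws.loglik(0.0)
        if ll_null > ll_max:
            theta, ll_max = 0.0, ll_null
        lam = max(-2.0 * (ll_null - ll_max), 0.0)
        from scipy.stats import chi2

        records.append({
            "taxon_a": a, "taxon_b": b, "theta": theta,
            "lambda": lam, "p_raw": float(chi2.sf(lam, 1)),
            "at_boundary": bool(abs(theta) >= theta_bound - 1e-6),
        })

    edges = pd.DataFrame(records,
                         columns=["taxon_a", "taxon_b", "theta", "lambda",
                                  "p_raw", "at_boundary"])
    if len(edges):
        reject, p_adj = by_fdr(edges["p_raw"].to_numpy(), q)
        edges["p_adj"] = p_adj
        edges["significant"] = reject
    else:
        edges["p_adj"] = []
        edges["significant"] = []

    m = len(taxa)
    theta_m = pd.DataFrame(np.zeros((m, m)), index=taxa, columns=taxa)
    p_m = pd.DataFrame(np.full((m, m), np.nan), index=taxa, columns=taxa)
    padj_m = p_m.copy()
    adj = pd.DataFrame(np.zeros((m, m), dtype=bool), index=taxa, columns=taxa)
    for rec in edges.itertuples():
        a, b = rec.taxon_a, rec.taxon_b
        theta_m.loc[a, b] = theta_m.loc[b, a] = rec.theta
        p_m.loc[a, b] = p_m.loc[b, a] = rec.p_raw
        padj_m.loc[a, b] = padj_m.loc[b, a] = rec.p_adj
        adj.loc[a, b] = adj.loc[b, a] = bool(rec.significant)

    G = nx.Graph()
    G.add_nodes_from(taxa)
    for rec in edges[edges["significant"]].itertuples():
        G.add_edge(rec.taxon_a, rec.taxon_b, theta=rec.theta)

    return CovariationNetworkResult(
        taxa=taxa, theta_matrix=theta_m, pvalue_matrix=p_m, padj_matrix=padj_m,
        adjacency=adj, edges=edges, q=q,
        failures=pd.DataFrame(failures, columns=["taxon_a", "taxon_b", "reason"]),
        graph=G,
        diagnostics={"n_tested": len(edges), "n_failed": len(failures),
                     "n_significant": int(edges["significant"].sum()) if len(edges) else 0,
                     "n_clamped": n_clamped},
    )


def _dissimilarity(result: CovariationNetworkResult) -> np.ndarray:
    """d(i, j) = 1 - |theta_w| / max|theta_w| on significant pairs, 1 otherwise."""
    W = result.weighted_adjacency().to_numpy()
    absW = np.abs(W)
    mx = absW.max()
    if mx == 0.0:
        warnings.warn("no significant pairs: all dissimilarities equal, single cluster",
                      stacklevel=2)
        D = np.ones_like(absW)
    else:
        D = 1.0 - absW / mx
    np.fill_diagonal(D, 0.0)
    return D


def cluster_network(result: CovariationNetworkResult, n_clusters: int = 3,
                    method: str = "complete") -> CovariationNetworkResult:
    """Complete agglomerative clustering of the theta-weighted adjacency.

    The dendrogram is cut to ``n_clusters`` groups; labels and leaf order are
    stored on the result (ties broken deterministically by taxon label
    order).
    """
    if len(result.taxa) < 2:
        raise ValueError("clustering needs at least 2 taxa")
    D = _dissimilarity(result)
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    result.cluster_labels = pd.Series(labels, index=result.taxa, name="cluster")
    result.leaf_order = [result.taxa[i] for i in leaves_list(Z)]
    return result


def graph_summaries(result: CovariationNetworkResult) -> dict:
    """Per-node centralities (normalized) and global statistics of the edge graph.

    On a disconnected graph, diameter and mean distance are computed on the
    largest connected component and flagged.
    """
    G = result.graph
    m = G.number_of_nodes()
    per_node = pd.DataFrame(index=result.taxa)
    per_node["degree"] = pd.Series(nx.degree_centrality(G))          # degree/(m-1)
    per_node["closeness"] = pd.Series(nx.closeness_centrality(G))
    per_node["betweenness"] = pd.Series(nx.betweenness_centrality(G))
    if G.number_of_edges() > 0:
        try:
            per_node["eigenvector"] = pd.Series(nx.eigenvector_centrality_numpy(G))
        except (nx.NetworkXException, TypeError):
            per_node["eigenvector"] = np.nan
    else:
        per_node["eigenvector"] = 0.0

    out = {
        "per_node": per_node,
        "node_means": per_node.mean().to_dict(),
        "node_sds": per_node.std(ddof=1).to_dict(),
        "density": nx.density(G),
        "average_clustering": nx.average_clustering(G) if m else np.nan,
        "largest_component_only": False,
    }
    if G.number_of_edges() == 0:
        out["diameter"] = None
        out["mean_distance"] = None
        out["largest_component_only"] = True
    else:
        if nx.is_connected(G):
            H = G
        else:
            H = G.subgraph(max(nx.connected_components(G), key=len))
            out["largest_component_only"] = True
        out["diameter"] = nx.diameter(H)
        out["mean_distance"] = nx.average_shortest_path_length(H)
    if result.cluster_labels is not None and G.number_of_edges() > 0:
        parts = [
            {t for t in result.taxa if result.cluster_labels[t] == c}
            for c in sorted(result.cluster_labels.unique())
        ]
        out["modularity"] = nx.algorithms.community.modularity(G, parts)
    return out


def _er_modularity(G: nx.Graph, n_clusters: int) -> float:
    """Modularity of an ER graph under the same clustering procedure (adjacency
    dissimilarity, complete linkage, cut at n_clusters)."""
    nodes = sorted(G.nodes())
    A = nx.to_numpy_array(G, nodelist=nodes)
    D = 1.0 - A
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    parts = [
        {nodes[i] for i in range(len(nodes)) if labels[i] == c}
        for c in np.unique(labels)
    ]
    if G.number_of_edges() == 0:
        return 0.0
    return nx.algorithms.community.modularity(G, parts)


def er_null_comparison(result: CovariationNetworkResult, n_graphs: int = 1000,
                       seed: Optional[int] = None, n_clusters: int = 3) -> dict:
    """Erdos-Renyi G(m, M) null ensemble with the observed node and edge counts.

    Returns null distributions of the average clustering coefficient and of
    the modularity under the same clustering procedure, plus the cumulative
    degree distribution, with empirical two-sided p-values (fraction of null
    graphs at least as far from the null mean as the observed value).
    """
    G = result.graph
    m, M = G.number_of_nodes(), G.number_of_edges()
    rng = np.random.default_rng(seed)
    clust = np.empty(n_graphs)
    mod = np.empty(n_graphs)
    degrees = []
    for g in range(n_graphs):
        H = nx.gnm_random_graph(m, M, seed=int(rng.integers(0, 2**31 - 1)))
        clust[g] = nx.average_clustering(H)
        mod[g] = _er_modularity(H, n_clusters)
        degrees.append(sorted(d for _, d in H.degree()))

    obs_clust = nx.average_clustering(G)
    obs_mod = (_er_modularity_observed(result, n_clusters)
               if result.cluster_labels is not None else _er_modularity(G, n_clusters))

    def pval(null: np.ndarray, obs: float) -> float:
        center = null.mean()
        return float(np.mean(np.abs(null - center) >= abs(obs - center) - 1e-15))

    return {
        "null_clustering": clust,
        "null_modularity": mod,
        "null_degree_distributions": degrees,
        "observed_clustering": obs_clust,
        "observed_modularity": obs_mod,
        "p_clustering": pval(clust, obs_clust),
        "p_modularity": pval(mod, obs_mod),
    }


def _er_modularity_observed(result: CovariationNetworkResult, n_clusters: int) -> float:
    G = result.graph
    if G.number_of_edges() == 0:
        return 0.0
    parts = [
        {t for t in result.taxa if result.cluster_labels[t] == c}
        for c in sorted(result.cluster_labels.unique())
    ]
    return nx.algorithms.community.modularity(G, parts)


def overlap_coefficient(a: set, b: set) -> float:
    """|A ∩ B| / min(|A|, |B|); 0 when either set is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def dice_coefficient(a: set, b: set) -> float:
    """2 |A ∩ B| / (|A| + |B|); 0 when both sets are empty."""
    if not a and not b:
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def bootstrap_consistency(table: pd.DataFrame, covariates: Optional[pd.DataFrame] = None,
                          q: float = 0.01, n_boot: int = 50,
                          seed: Optional[int] = None, *,
                          baseline: Optional[CovariationNetworkResult] = None) -> dict:
    """Row-bootstrap stability of the FDR edge set.

    Resamples samples (rows) with replacement ``n_boot`` times, reruns the
    all-pairs analysis with BY control at ``q``, and summarizes edge-set
    agreement with the original data via overlap and Dice coefficients, plus
    each pair's selection frequency. Degenerate replicates are skipped and
    counted.
    """
    table = pd.DataFrame(table)
    rng = np.random.default_rng(seed)
    if baseline is None:
        baseline = pairwise_analysis(table, covariates, q)
    base_edges = baseline.edge_set
    n = table.shape[0]
    overlaps, dices, sizes = [], [], []
    freq: dict = {}
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = table.iloc[idx].reset_index(drop=True)
        cov_b = None if covariates is None else pd.DataFrame(covariates).iloc[idx].reset_index(drop=True)
        try:
            res = pairwise_analysis(boot, cov_b, q)
        except (InsufficientDataError, ValueError, DegenerateDataError):
            skipped += 1
            continue
        es = res.edge_set
        overlaps.append(overlap_coefficient(base_edges, es))
        dices.append(dice_coefficient(base_edges, es))
        sizes.append(len(es))
        for e in es:
            freq[e] = freq.get(e, 0) + 1
    n_ok = len(overlaps)
    freq_df = pd.DataFrame(
        [(a, b, c / n_ok if n_ok else np.nan) for (a, b), c in sorted(freq.items())],
        columns=["taxon_a", "taxon_b", "selection_frequency"],
    )
    return {
        "overlap_mean": float(np.mean(overlaps)) if n_ok else np.nan,
        "overlap_sd": float(np.std(overlaps, ddof=1)) if n_ok > 1 else np.nan,
        "dice_mean": float(np.mean(dices)) if n_ok else np.nan,
        "dice_sd": float(np.std(dices, ddof=1)) if n_ok > 1 else np.nan,
        "edge_counts": sizes,
        "selection_frequency": freq_df,
        "n_completed": n_ok,
        "n_skipped": skipped,
        "baseline_edges": base_edges,
    }


class CovariationNetwork(BaseEstimator):
    """Covariation-network estimator over a samples x taxa abundance table.

    Fitting runs the all-pairs two-stage Frank-copula LRT with BY FDR at
    level ``q``, then complete-linkage clustering into ``n_clusters`` groups.

    Attributes (after ``fit``)
    --------------------------
    result_ : CovariationNetworkResult with matrices, edges and the graph
    theta_matrix_, adjacency_ : convenience views
    labels_ : per-taxon cluster assignment (array, taxon order of X)
    summaries_ : per-node and global graph statistics
    """

    def __init__(self, q: float = 0.01, n_clusters: int = 3,
                 theta_bound: float = THETA_MAX, covariate_parts: tuple = ("p", "mu")):
        self.q = q
        self.n_clusters = n_clusters
        self.theta_bound = theta_bound
        self.covariate_parts = covariate_parts

    def fit(self, X, y=None, covariates: Optional[pd.DataFrame] = None):
        result = pairwise_analysis(
            pd.DataFrame(X), covariates, self.q,
            theta_bound=self.theta_bound, covariate_parts=self.covariate_parts,
        )
        cluster_network(result, self.n_clusters)
        self.result_ = result
        self.theta_matrix_ = result.theta_matrix
        self.adjacency_ = result.adjacency
        self.labels_ = result.cluster_labels.to_numpy()
        self.summaries_ = graph_summaries(result)
        self.n_features_in_ = len(result.taxa)
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_
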