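"""Coding-noncoding co-expression network and Markov clustering.

Edges are all-pairs Pearson correlations whose Bonferroni-adjusted p-value
clears a cutoff; Markov clustering (MCL) with configurable inflation then
partitions the graph, and clusters are assessed for enrichment of a
special feature set (Fisher) or annotation terms (hypergeometric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoexpressionClustering",
    "prefilter_low_expression",
    "build_graph",
    "mcl_cluster",
    "filter_and_link_clusters",
    "cluster_set_enrichment",
    "term_enrichment",
    "edge_affinity",
]

AFFINITY_CAP = 300.0


@dataclass
class CoexpressionClustering:
    """MCL cluster membership with a size-based retention mask."""

    clusters: dict[int, list[str]]
    converged: bool = True
    retained: list[int] = field(default_factory=list)
    inter_cluster_edges: int | None = None

    def labels(self) -> pd.Series:
        rows = {n: cid for cid, members in self.clusters.items() for n in members}
        return pd.Series(rows, name="cluster")


def prefilter_low_expression(expr: pd.DataFrame,
                             drop_fraction: float = 0.20) -> list[str]:
    """Features whose maximum expression escapes the bottom quantile.

    Ties are broken by feature id so exactly ``floor(drop_fraction * n)``
    features are removed, deterministically.
    """
    if len(expr) < 5:
        raise ValueError("need >= 5 features")
    n_drop = int(np.floor(drop_fraction * len(expr)))
    if n_drop == 0:
        return list(expr.index)
    ranked = (
        expr.max(axis=1)
        .rename("max_expr")
        .rename_axis("feature")
        .reset_index()
        .sort_values(["max_expr", "feature"], kind="mergesort")
    )
    dropped = set(ranked["feature"].iloc[:n_drop])
    return [f for f in expr.index if f not in dropped]


def build_graph(expr: pd.DataFrame, alpha: float = 0.01,
                node_types: dict[str, str] | None = None,
                logger=None) -> nx.Graph:
    """All-pairs Pearson graph with a Bonferroni edge cutoff.

    p-values come from the exact t transform of r with n-2 degrees of
    freedom; the Bonferroni multiplier is the number of tested pairs.
    Zero-variance features are excluded. Edge attributes: ``r``, ``p_adj``.
    """
    n_samples = expr.shape[1]
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    sd = expr.std(axis=1, ddof=1)
    drop = sd[sd == 0].index
    if len(drop) and logger is not None:
        logger.info("excluding %d zero-variance features", len(drop))
    x = expr.drop(index=drop)
    feats = list(x.index)
    n = len(feats)
    graph = nx.Graph()
    for f in feats:
        graph.add_node(f, kind=(node_types or {}).get(f, "feature"))
    if n < 2:
        return graph

    r = np.corrcoef(x.to_numpy(dtype=float))
    np.clip(r, -1.0, 1.0, out=r)
    dof = n_samples - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    n_pairs = n * (n - 1) // 2
    p_adj = np.minimum(p * n_pairs, 1.0)

    iu, ju = np.triu_indices(n, k=1)
    keep = p_adj[iu, ju] < alpha
    for i, j in zip(iu[keep], ju[keep]):
        graph.add_edge(feats[i], feats[j], r=float(r[i, j]),
                       p_adj=float(p_adj[i, j]))
    return graph


def edge_affinity(p_adj: float) -> float:
    """MCL affinity from an adjusted p-value: -log10(p), capped."""
    if p_adj <= 0:
        return AFFINITY_CAP
    return min(-np.log10(p_adj), AFFINITY_CAP)


def mcl_cluster(graph: nx.Graph, inflation: float = 2.4,
                prune_below: float = 1e-5, max_iter: int = 200,
                tol: float = 1e-8) -> CoexpressionClustering:
    """Markov clustering of the co-expression graph.

    The column-stochastic transition matrix is built from edge affinities
    (-log10 adjusted p) plus unit self-loops, then expansion (matrix
    square) and inflation (elementwise power + renormalisation) alternate,
    pruning entries below ``prune_below``, until idempotence. Attractor
    rows define the clusters. Deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = edge_affinity(data["p_adj"]) if "p_adj" in data \
            else float(data.get("weight", 1.0))
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    np.fill_diagonal(m, np.maximum(m.max(axis=0), 1.0))
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune_below] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated

    # attractors: nodes with mass on their own row; each attractor row's
    # support is one cluster; overlapping supports merge
    attractors = np.where(np.diag(m) > 1e-6)[0]
    clusters: list[set[int]] = []
    for a in attractors:
        members = set(np.where(m[a] > 1e-6)[0]) | {a}
        merged = None
        for c in clusters:
            if c & members:
                c |= members
                merged = c
                break
        if merged is None:
            clusters.append(members)
    # repeat merge pass in case a later attractor bridged two clusters
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    covered = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in covered:
            clusters.append({i})
    clusters.sort(key=lambda c: (-len(c), min(c)))
    out = {cid: sorted(nodes[i] for i in members)
           for cid, members in enumerate(clusters)}
    return CoexpressionClustering(out, converged=converged)


def filter_and_link_clusters(clustering: CoexpressionClustering,
                             graph: nx.Graph,
                             min_size: int = 100) -> CoexpressionClustering:
    """Retain clusters of >= ``min_size`` members and count graph edges
    crossing between different retained clusters."""
    retained = [cid for cid, members in clustering.clusters.items()
                if len(members) >= min_size]
    member_of = {}
    for cid in retained:
        for node in clustering.clusters[cid]:
            member_of[node] = cid
    crossing = 0
    for a, b in graph.edges:
        ca, cb = member_of.get(a), member_of.get(b)
        if ca is not None and cb is not None and ca != cb:
            crossing += 1
    clustering.retained = retained
    clustering.inter_cluster_edges = crossing
    return clustering


def cluster_set_enrichment(clustering: CoexpressionClustering,
                           special_set: set[str],
                           universe: set[str]) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a feature set per retained
    cluster."""
    if not special_set <= universe:
        raise ValueError("special_set must be a subset of the universe")
    rows = []
    cids = clustering.retained or list(clustering.clusters)
    for cid in cids:
        members = set(clustering.clusters[cid]) & universe
        if not members:
            continue
        a = len(members & special_set)
        b = len(members) - a
        c = len(special_set) - a
        d = len(universe) - len(members) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"cluster": cid, "n_members": len(members),
                     "n_special": a, "p": float(p)})
    return pd.DataFrame(rows, columns=["cluster", "n_members", "n_special", "p"])


def term_enrichment(cluster_genes: set[str], term_map: dict[str, set[str]],
                    universe: set[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of annotation terms in a gene
    cluster, with BH q as a convenience column."""
    cluster = set(cluster_genes) & universe
    rows = []
    N = len(universe)
    n = len(cluster)
    if n == 0:
        return pd.DataFrame(columns=["term", "n_term", "n_overlap", "p", "q"])
    for term, genes in sorted(term_map.items()):
        K = len(genes & universe)
        if K == 0:
            continue
        k = len(genes & cluster)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "n_term": K, "n_overlap": k, "p": p})
    df = pd.DataFrame(rows, columns=["term", "n_term", "n_overlap", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df
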