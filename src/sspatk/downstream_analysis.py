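"""Downstream analyses of pathway score matrices.

Case-study machinery: Ward hierarchical clustering of samples in
pathway-score space with adjusted-Rand-index evaluation, cumulative
ARI curves over progressively larger significant-feature prefixes, and
Spearman pathway-pathway correlation networks with per-group mean
scores as node attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .sspa_methods import PathwayScoreMatrix

__all__ = [
    "PathwayNetwork",
    "cluster_scores",
    "adjusted_rand_index",
    "cumulative_ari_curve",
    "build_correlation_network",
]


@dataclass
class PathwayNetwork:
    """Pathway-pathway Spearman correlation network.

    Nodes carry the pathway name, a 2-way Ward cluster id, and the mean
    standardized score per sample group; edges carry the Spearman rho
    (all >= the configured threshold).
    """

    graph: nx.Graph
    rho_min: float
    params: dict = field(default_factory=dict)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            (a, b, d["rho"]) for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "rho"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edge_list(self, path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)


def _as_frame(scores) -> pd.DataFrame:
    if isinstance(scores, PathwayScoreMatrix):
        return scores.scores
    if hasattr(scores, "data"):  # MetaboliteMatrix
        return scores.data
    return pd.DataFrame(scores)


def _standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=1)
    sd = sd.replace(0, np.nan)
    return (df - df.mean(axis=0)) / sd


def cluster_scores(scores, n_clusters: int = 2) -> pd.Series:
    """Agglomerative Ward clustering (Euclidean) of samples, tree cut at
    ``n_clusters``.  Columns are standardized (mean 0, sd 1) first."""
    df = _as_frame(scores)
    if n_clusters > df.shape[0]:
        raise ValueError("more clusters than samples")
    Z = _standardize_columns(df).fillna(0.0).to_numpy()
    tree = linkage(Z, method="ward", metric="euclidean")
    labels = fcluster(tree, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=df.index, name="cluster")


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected Rand index between two partitions; can be < 0."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def cumulative_ari_curve(
    features,
    labels: pd.Series,
    q_threshold: float = 0.05,
    n_clusters: int = 2,
) -> pd.DataFrame:
    """Clustering quality as significant features are added one by one.

    Features (metabolites or pathway scores) are ranked by BH q-value
    from two-group t-tests; those with q <= ``q_threshold`` are added in
    order of increasing q, re-clustering at every prefix and recording
    the ARI against the true labels.  Returns a DataFrame with columns
    ``n_features`` and ``ari``.
    """
    df = _as_frame(features)
    labels = pd.Series(labels).loc[df.index]
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("binary labels required")
    mask = (labels == levels[0]).to_numpy()
    X = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(X[mask], X[~mask], axis=0)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    order = np.argsort(q, kind="stable")
    selected = [df.columns[i] for i in order if q[i] <= q_threshold]
    if not selected:
        warnings.warn("no features significant at the q threshold", RuntimeWarning)
        return pd.DataFrame(columns=["n_features", "ari"])
    rows = []
    for j in range(1, len(selected) + 1):
        cl = cluster_scores(df[selected[:j]], n_clusters=n_clusters)
        rows.append((j, adjusted_rand_index(cl.to_numpy(), labels.to_numpy())))
    return pd.DataFrame(rows, columns=["n_features", "ari"])


def build_correlation_network(
    scores: PathwayScoreMatrix,
    labels: pd.Series,
    top_n: int = 50,
    rho_min: float = 0.4,
    absolute: bool = False,
) -> PathwayNetwork:
    """Spearman correlation network over the most group-discriminating
    pathways.

    The ``top_n`` pathways with smallest two-group t-test p-values are
    selected (ties broken by pathway id); nodes get a 2-branch Ward
    cluster id and the mean standardized score per sample group; edges
    connect pathway pairs with Spearman rho >= ``rho_min`` (signed by
    default; set ``absolute`` to threshold |rho|)."""
    df = scores.scores
    if top_n > df.shape[1]:
        raise ValueError("top_n exceeds the number of pathways")
    labels = pd.Series(labels).loc[df.index]
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("at least two groups required")
    mask = (labels == levels[0]).to_numpy()
    X = df.to_numpy(dtype=float)
    if len(levels) == 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(X[mask], X[~mask], axis=0)
    else:
        # multi-group selection falls back to one-way ANOVA
        groups = [X[(labels == g).to_numpy()] for g in levels]
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*groups)
    p = np.nan_to_num(p, nan=1.0)
    ranking = sorted(zip(p, df.columns))
    selected = [c for _, c in ranking[:top_n]]
    sub = df[selected]

    std = _standardize_columns(sub)
    cluster_of = pd.Series(
        fcluster(
            linkage(std.fillna(0.0).to_numpy().T, method="ward"),
            t=2,
            criterion="maxclust",
        ),
        index=selected,
    )
    group_means = {
        g: std[(labels == g).to_numpy()].mean(axis=0) for g in levels
    }

    constant = sub.std(axis=0, ddof=1) == 0
    if constant.any():
        warnings.warn(
            f"constant score columns kept edgeless: "
            f"{list(sub.columns[constant])}",
            RuntimeWarning,
        )
    rho = stats.spearmanr(sub.to_numpy()).statistic
    rho = np.atleast_2d(rho)

    g = nx.Graph()
    for pid in selected:
        attrs = {"name": pid, "cluster": int(cluster_of[pid])}
        for grp in levels:
            val = group_means[grp][pid]
            attrs[f"mean_score_{grp}"] = float(0.0 if np.isnan(val) else val)
        g.add_node(pid, **attrs)
    for i in range(len(selected)):
        for j in range(i + 1, len(selected)):
            if constant.iloc[i] or constant.iloc[j]:
                continue
            r = rho[i, j]
            val = abs(r) if absolute else r
            if not np.isnan(r) and val >= rho_min:
                g.add_edge(selected[i], selected[j], rho=float(r))
    return PathwayNetwork(
        graph=g,
        rho_min=rho_min,
        params={"top_n": top_n, "absolute": absolute},
    )
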