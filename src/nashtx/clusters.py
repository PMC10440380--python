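"""Group geometric means, k-means clustering and per-cluster summaries.

Interaction genes are summarized as a gene x 4 matrix of geometric mean
expression over the diet x time groups, clustered with k-means (k = 8 by
default, matching the eight expression archetypes of the study heatmap),
and each cluster is collapsed to one value per group (the median across
member genes by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import GROUP_ORDER, DesignTable, ExprMatrix

logger = logging.getLogger("nashtx")


@dataclass
class GeneClusterMap:
    """gene_id -> cluster label in 1..k, plus the fit's inertia and seed."""

    labels: pd.Series  # index gene_id, values int 1..k
    k: int
    seed: int
    inertia: float

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def group_geometric_means(
    expr: ExprMatrix, design: DesignTable, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene geometric mean expression in each diet x time group.

    Computed as 2^(mean log2(v + pseudocount)) - pseudocount, floored at 0;
    the pseudocount guards genes with zero expression in some sample.
    Columns follow the canonical group order LFD-1wk, WD-1wk, LFD-40wk,
    WD-40wk.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if expr.scale == "log2":
        raise ValueError("group_geometric_means expects normalized-scale values")
    cols = {s: i for i, s in enumerate(expr.sample_ids)}
    out = {}
    for g in GROUP_ORDER:
        diet, timelab = g.split("-")
        time = int(timelab.removesuffix("wk"))
        idx = [cols[s] for s in design.samples_for(diet=diet, time=time)]
        if not idx:
            raise ValueError(f"group {g} has no samples")
        logm = np.log2(expr.values[:, idx] + pseudocount).mean(axis=1)
        out[g] = np.maximum(2.0**logm - pseudocount, 0.0)
    return pd.DataFrame(out, index=pd.Index(expr.gene_ids, name="gene_id"))


def kmeans_cluster(
    means: pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = True,
) -> GeneClusterMap:
    """K-means over per-gene group-mean profiles.

    Rows are z-scored per gene when ``standardize`` is set (so clusters
    capture profile shape, not absolute expression; flat genes map to the
    zero profile).  Lloyd's algorithm with k-means++ initialization, best of
    ``n_init`` restarts.  Clusters are relabeled 1..k by descending member
    count, ties broken by the smallest member gene id.
    """
    n_genes = means.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_genes < k:
        raise ValueError(f"need at least k={k} genes, got {n_genes}")
    X = means.to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)

    # deterministic relabeling: biggest cluster first, ties by member gene id
    order_key = []
    for c in range(k):
        member_genes = means.index[raw == c]
        first = min(member_genes) if len(member_genes) else ""
        order_key.append((-len(member_genes), first, c))
    relabel = {c: i + 1 for i, (_, _, c) in enumerate(sorted(order_key))}
    labels = pd.Series([relabel[c] for c in raw], index=means.index, name="cluster")
    return GeneClusterMap(labels=labels, k=k, seed=seed, inertia=float(km.inertia_))


def summarize_clusters(
    means: pd.DataFrame, clusters: GeneClusterMap, stat: str = "median"
) -> pd.DataFrame:
    """One value per cluster and group: the ``stat`` over member genes.

    ``stat`` is ``median`` (default), ``mean`` or ``sum``.  An empty cluster
    yields a NaN row with a warning.  A ``n_genes`` column records cluster
    sizes.
    """
    if stat not in ("median", "mean", "sum"):
        raise ValueError("stat must be one of median, mean, sum")
    if not set(means.index) <= set(clusters.labels.index):
        raise ValueError("cluster map does not cover all genes in the matrix")
    rows = []
    for c in range(1, clusters.k + 1):
        genes = [g for g in clusters.members(c) if g in means.index]
        if not genes:
            logger.warning("cluster %d is empty; summary row is NaN", c)
            rows.append(pd.Series(np.nan, index=means.columns, name=c))
            continue
        sub = means.loc[genes]
        rows.append(getattr(sub, stat)(axis=0).rename(c))
    out = pd.DataFrame(rows)
    out.index.name = "cluster"
    out["n_genes"] = [
        len([g for g in clusters.members(c) if g in means.index])
        for c in out.index
    ]
    return out


def plot_cluster_heatmap(
    means: pd.DataFrame, clusters: GeneClusterMap, path, standardize: bool = True
):
    """Optional PNG heatmap: genes ordered by cluster, groups as columns."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clusters.labels.sort_values(kind="stable").index
    X = means.loc[order].to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    fig, ax = plt.subplots(figsize=(4, 8))
    im = ax.imshow(X, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xticks(range(len(means.columns)), means.columns, rotation=90)
    ax.set_yticks([])
    ax.set_ylabel("genes (by cluster)")
    fig.colorbar(im, ax=ax, label="row z-score" if standardize else "geometric mean")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
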