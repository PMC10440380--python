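"""Single-cell reanalysis: filtering, normalization, clustering, markers.

The marker rule operationalizes cell-type-unique expression:
a gene is a marker of a cluster when its mean library-size-normalized UMI in
that cluster exceeds ``umi_min`` (1.0 by default), the one-sided Wilcoxon
rank-sum test against all other cells is significant after BH correction,
the log2 fold change vs the rest is at least ``min_log2fc`` — and, with the
uniqueness guarantee, when the gene qualifies in exactly one cluster and
stays at or below ``umi_min`` in every other cluster ("uniquely expressed").
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, MarkerCatalog, ScExprMatrix

logger = logging.getLogger("nashtx")

FC_EPS = 1e-9  # guards fold-change ratios against division by zero


def filter_sc(
    umis: CountMatrix, min_genes_per_cell: int = 200, min_cells_per_gene: int = 3
) -> CountMatrix:
    """Drop shallow cells, then rarely detected genes (in that order)."""
    if umis.role != "sc":
        raise ValueError("filter_sc expects a cell x gene matrix (role='sc')")
    X = umis.values
    keep_cells = (X > 0).sum(axis=1) >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError("all cells removed by min_genes_per_cell filter")
    X = X[keep_cells]
    keep_genes = (X > 0).sum(axis=0) >= min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("all genes removed by min_cells_per_gene filter")
    logger.info(
        "filter_sc: kept %d/%d cells and %d/%d genes",
        int(keep_cells.sum()), len(keep_cells),
        int(keep_genes.sum()), len(keep_genes),
    )
    return CountMatrix(
        X[:, keep_genes],
        [c for c, k in zip(umis.cell_ids, keep_cells) if k],
        [g for g, k in zip(umis.gene_ids, keep_genes) if k],
        role="sc",
    )


def normalize_umis(umis: CountMatrix, scale: float = 10000.0) -> ScExprMatrix:
    """Counts-per-``scale`` per cell; the normalized-UMI quantity."""
    if umis.role != "sc":
        raise ValueError("normalize_umis expects a cell x gene matrix")
    lib = umis.values.sum(axis=1).astype(float)
    if (lib == 0).any():
        zero = [c for c, s in zip(umis.cell_ids, lib) if s == 0]
        raise ValueError(f"cells with zero total UMIs: {zero[:5]}")
    norm = umis.values / lib[:, None] * scale
    return ScExprMatrix(norm, list(umis.cell_ids), list(umis.gene_ids), lib)


def cluster_cells(
    expr: ScExprMatrix,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    method: str = "graph",
    resolution_or_k: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Cluster cells: log1p -> highly variable genes -> PCA -> graph/k-means.

    ``method='graph'`` runs Leiden community detection on a k-nearest-
    neighbor graph of the PCA space; ``method='kmeans'`` runs k-means with
    k = int(resolution_or_k).  Deterministic given the seed.  Returns a
    label Series indexed by cell id.
    """
    import anndata as ad
    import scanpy as sc

    n_cells, n_genes = expr.shape
    if n_cells < 2:
        raise ValueError("need at least two cells to cluster")
    n_pcs_eff = min(n_pcs, n_cells - 1, n_genes - 1)
    if n_pcs > min(n_cells, n_genes):
        raise ValueError("n_pcs exceeds the data dimensions")

    adata = ad.AnnData(
        X=expr.values.copy(),
        obs=pd.DataFrame(index=pd.Index(expr.cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(expr.gene_ids, name="gene_id")),
    )
    sc.pp.log1p(adata)
    if n_genes > n_hvg:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    sc.tl.pca(adata, n_comps=n_pcs_eff, svd_solver="arpack", random_state=seed)

    if method == "graph":
        sc.pp.neighbors(
            adata, n_neighbors=min(15, n_cells - 1), n_pcs=n_pcs_eff,
            random_state=seed,
        )
        sc.tl.leiden(
            adata, resolution=float(resolution_or_k), random_state=seed,
            key_added="cluster", flavor="leidenalg",
        )
        labels = adata.obs["cluster"].astype(str)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        k = int(resolution_or_k)
        if k < 1:
            raise ValueError("k must be >= 1 for method='kmeans'")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = pd.Series(
            km.fit_predict(adata.obsm["X_pca"]).astype(str), index=adata.obs_names
        )
    else:
        raise ValueError("method must be 'graph' or 'kmeans'")
    out = pd.Series(labels.values, index=list(expr.cell_ids), name="cluster")
    logger.info("cluster_cells (%s): %d clusters over %d cells",
                method, out.nunique(), n_cells)
    return out


def derive_markers(
    expr: ScExprMatrix,
    labels: pd.Series,
    umi_min: float = 1.0,
    min_log2fc: float = 1.0,
    q_max: float = 0.05,
    unique: bool = True,
) -> MarkerCatalog:
    """Per-cluster marker genes under the uniqueness rule (see module docs).

    BH correction is applied within each cluster's gene screen.  Clusters
    with fewer than two cells are excluded from testing (warning) but their
    mean expression still counts against other clusters' uniqueness.
    """
    from .de import bh_fdr

    labels = labels.reindex(expr.cell_ids)
    if labels.isna().any():
        raise ValueError("labels do not cover every cell in the matrix")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two clusters to derive markers")

    X = expr.values
    genes = np.asarray(expr.gene_ids)
    mean_by_type = {}
    testable = []
    for t in types:
        mask = (labels == t).to_numpy()
        mean_by_type[t] = X[mask].mean(axis=0)
        if mask.sum() >= 2 and (~mask).sum() >= 2:
            testable.append(t)
        else:
            logger.warning("cluster %s has <2 cells; excluded from marker tests", t)

    candidate = {}
    records = {}
    for t in testable:
        mask = (labels == t).to_numpy()
        m_in, m_rest = mean_by_type[t], X[~mask].mean(axis=0)
        log2fc = np.log2((m_in + FC_EPS) / (m_rest + FC_EPS))
        res = stats.mannwhitneyu(
            X[mask], X[~mask], axis=0, alternative="greater", method="asymptotic"
        )
        q = bh_fdr(res.pvalue)
        cand = (m_in > umi_min) & (q <= q_max) & (log2fc >= min_log2fc)
        candidate[t] = cand
        records[t] = (m_in, log2fc, q)

    rows = []
    n_dropped_unique = 0
    for t in testable:
        cand = candidate[t]
        m_in, log2fc, q = records[t]
        for i in np.flatnonzero(cand):
            if unique:
                n_cand = sum(candidate[u][i] for u in testable)
                elsewhere_high = any(
                    mean_by_type[u][i] > umi_min for u in types if u != t
                )
                if n_cand != 1 or elsewhere_high:
                    n_dropped_unique += 1
                    continue
            rows.append(
                {
                    "cell_type": t,
                    "gene_id": genes[i],
                    "mean_norm_umi": float(m_in[i]),
                    "log2fc": float(log2fc[i]),
                    "q_value": float(q[i]),
                }
            )
    if unique and n_dropped_unique:
        logger.info("derive_markers: %d candidate(s) dropped by uniqueness rule",
                    n_dropped_unique)
    table = pd.DataFrame(
        rows, columns=["cell_type", "gene_id", "mean_norm_umi", "log2fc", "q_value"]
    )
    if len(table):
        table = table.sort_values(
            ["cell_type", "log2fc"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    return MarkerCatalog(table=table, unique=unique, umi_min=umi_min)


def subcluster(
    expr: ScExprMatrix,
    labels: pd.Series,
    parent_type: str,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    method: str = "graph",
    resolution_or_k: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Re-cluster the cells of one parent cluster; labels become
    ``parent/sub_<i>`` while all other cells keep their original labels."""
    labels = labels.reindex(expr.cell_ids)
    mask = (labels == parent_type).to_numpy()
    if not mask.any():
        raise ValueError(f"parent type {parent_type!r} not present in labels")
    sub = ScExprMatrix(
        expr.values[mask],
        [c for c, m in zip(expr.cell_ids, mask) if m],
        list(expr.gene_ids),
        expr.library_sizes[mask],
    )
    sub_labels = cluster_cells(
        sub, n_hvg=n_hvg, n_pcs=n_pcs, method=method,
        resolution_or_k=resolution_or_k, seed=seed,
    )
    out = labels.copy()
    out.loc[sub_labels.index] = [f"{parent_type}/sub_{v}" for v in sub_labels]
    out.name = "cluster"
    return out
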