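"""Normalization and the two bulk screens.

Two complementary screens drive the analysis:

* per-timepoint differential expression — Welch's unpaired t-test on log2
  quantile-normalized expression, WD vs LFD with sexes pooled, called at
  fold change >= 2 (up) or <= 0.5 (down) with Benjamini-Hochberg FDR <= 0.1;
* a diet x time interaction screen — fixed-effects 2x2 ANOVA per gene, the
  interaction F on (1, N-4) degrees of freedom, BH-corrected.

All thresholds are exposed as parameters; the defaults above are the
conventional criteria for this design.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, DesignTable, ExprMatrix, OverlapSummary

logger = logging.getLogger("nashtx")


# ---------------------------------------------------------------- normalization

def quantile_normalize(counts: CountMatrix | ExprMatrix) -> ExprMatrix:
    """Quantile-normalize columns to the mean sorted profile.

    After normalization every sample has the identical sorted value vector
    (the row-wise mean of the per-column sorted values).  Ties within a
    column receive the mean of the reference values at their rank positions.
    """
    X = np.asarray(counts.values, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    ref = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        uniq, inv, cnt = np.unique(X[:, j], return_inverse=True, return_counts=True)
        ends = np.cumsum(cnt)
        starts = ends - cnt
        block_means = (csum[ends] - csum[starts]) / cnt
        out[:, j] = block_means[inv]
    return ExprMatrix(out, list(counts.gene_ids), list(counts.sample_ids),
                      scale="normalized")


def log2_transform(expr: ExprMatrix, pseudocount: float = 1.0) -> ExprMatrix:
    """v -> log2(v + pseudocount); tags the result as log2 scale."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (expr.values < 0).any():
        raise ValueError("expression values must be non-negative")
    return ExprMatrix(np.log2(expr.values + pseudocount), list(expr.gene_ids),
                      list(expr.sample_ids), scale="log2")


# ------------------------------------------------------------------- BH FDR

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1 and mapped back to input
    order.  NaN entries are passed through and excluded from the ranking.
    Ties are broken by input position (stable) for reproducibility.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


# --------------------------------------------------------- per-timepoint DE

def de_per_timepoint(
    expr: ExprMatrix,
    design: DesignTable,
    time: int,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    fdr_max: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """WD vs LFD Welch t-test per gene at one timepoint, sexes pooled.

    Returns a table indexed by gene with geometric group means (normalized
    units), fold change (WD/LFD), log2fc, p, BH q and the call
    (``up``/``down``/``ns``).  Thresholds are inclusive.  Genes whose Welch
    denominator is zero (no variance in either group) get p = NaN and
    ``ns``.
    """
    if expr.scale != "log2":
        raise ValueError("de_per_timepoint expects a log2-scale matrix")
    cols = {s: i for i, s in enumerate(expr.sample_ids)}
    lfd = [cols[s] for s in design.samples_for(diet="LFD", time=time)]
    wd = [cols[s] for s in design.samples_for(diet="WD", time=time)]
    if len(lfd) < 2 or len(wd) < 2:
        raise ValueError(f"need >=2 samples per diet at {time} wk")

    xl, xw = expr.values[:, lfd], expr.values[:, wd]
    nl, nw = xl.shape[1], xw.shape[1]
    ml, mw = xl.mean(axis=1), xw.mean(axis=1)
    vl, vw = xl.var(axis=1, ddof=1), xw.var(axis=1, ddof=1)

    se2 = vl / nl + vw / nw
    log2fc = mw - ml
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / np.sqrt(se2)
        df = se2**2 / ((vl / nl) ** 2 / (nl - 1) + (vw / nw) ** 2 / (nw - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero within-group variance at %d wk: p set to NaN",
            int(degenerate.sum()), time,
        )
        p[degenerate] = np.nan

    q = bh_fdr(p)
    fc = 2.0**log2fc
    call = np.full(len(fc), "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        up = (fc >= fc_up) & (q <= fdr_max)  # NaN q compares False
        down = (fc <= fc_down) & (q <= fdr_max)
    call[up] = "up"
    call[down] = "down"

    geo = lambda m: np.maximum(2.0**m - pseudocount, 0.0)
    return pd.DataFrame(
        {
            "mean_expr_lfd": geo(ml),
            "mean_expr_wd": geo(mw),
            "fold_change": fc,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "call": call,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


# ------------------------------------------------------- interaction screen

def interaction_test(expr: ExprMatrix, design: DesignTable) -> pd.DataFrame:
    """Fixed-effects 2x2 diet x time ANOVA per gene.

    The interaction is tested through its contrast
    L = (WD40 - LFD40) - (WD1 - LFD1) on cell means, with
    F = L^2 / (MS_within * sum(1/n_ij)) on (1, N-4) degrees of freedom —
    exact for balanced and unbalanced designs and identical to the squared
    regression t for the interaction coefficient.
    """
    if expr.scale != "log2":
        raise ValueError("interaction_test expects a log2-scale matrix")
    cols = {s: i for i, s in enumerate(expr.sample_ids)}
    cells = {}
    for diet in ("LFD", "WD"):
        for time in (1, 40):
            idx = [cols[s] for s in design.samples_for(diet=diet, time=time)]
            if len(idx) < 2:
                raise ValueError(f"cell {diet}-{time}wk needs >=2 samples")
            cells[(diet, time)] = idx

    n_total = sum(len(v) for v in cells.values())
    df_within = n_total - 4
    means, ss_within, inv_n = {}, 0.0, 0.0
    for key, idx in cells.items():
        x = expr.values[:, idx]
        m = x.mean(axis=1)
        means[key] = m
        ss_within = ss_within + ((x - m[:, None]) ** 2).sum(axis=1)
        inv_n += 1.0 / len(idx)

    ms_within = ss_within / df_within
    L = (means[("WD", 40)] - means[("LFD", 40)]) - (means[("WD", 1)] - means[("LFD", 1)])
    with np.errstate(divide="ignore", invalid="ignore"):
        F = L**2 / (ms_within * inv_n)
    p = stats.f.sf(F, 1, df_within)
    undefined = ms_within == 0
    if undefined.any():
        logger.warning(
            "%d gene(s) with zero within-cell variance: interaction F undefined",
            int(undefined.sum()),
        )
        F[undefined] = np.nan
        p[undefined] = np.nan

    return pd.DataFrame(
        {
            "F_stat": F,
            "p_value": p,
            "q_value": bh_fdr(p),
            "log2fc_1wk": means[("WD", 1)] - means[("LFD", 1)],
            "log2fc_40wk": means[("WD", 40)] - means[("LFD", 40)],
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


# --------------------------------------------------------------- bookkeeping

def overlap_sets(de_1wk: pd.DataFrame, de_40wk: pd.DataFrame) -> OverlapSummary:
    """Directional call counts per timepoint and the genes called at both."""
    if set(de_1wk.index) != set(de_40wk.index):
        raise ValueError("DE tables must share one gene universe")
    called_1 = de_1wk.index[de_1wk["call"] != "ns"]
    called_40 = de_40wk.index[de_40wk["call"] != "ns"]
    common = sorted(set(called_1) & set(called_40))
    return OverlapSummary(
        n_total_1wk=len(called_1),
        n_up_1wk=int((de_1wk["call"] == "up").sum()),
        n_down_1wk=int((de_1wk["call"] == "down").sum()),
        n_total_40wk=len(called_40),
        n_up_40wk=int((de_40wk["call"] == "up").sum()),
        n_down_40wk=int((de_40wk["call"] == "down").sum()),
        n_common=len(common),
        common_genes=common,
        n_universe=len(de_1wk.index),
    )


def select_progressive_genes(
    interaction: pd.DataFrame,
    q_max: float = 0.1,
    fc1_min_log2: float = 0.0,
    fc40_min_log2: float = 1.0,
) -> list[str]:
    """Genes induced early and strongly upregulated late.

    Selects q <= q_max with log2fc strictly above ``fc1_min_log2`` at 1 wk
    (any induction) and strictly above ``fc40_min_log2`` at 40 wk (by
    default fold change > 2).
    """
    with np.errstate(invalid="ignore"):
        keep = (
            (interaction["q_value"] <= q_max)
            & (interaction["log2fc_1wk"] > fc1_min_log2)
            & (interaction["log2fc_40wk"] > fc40_min_log2)
        )
    return list(interaction.index[keep.fillna(False)])
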