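"""Gene-set enrichment: hypergeometric ORA, preranked GSEA, concordance.

ORA tests a query gene set against each named collection set with the
one-sided hypergeometric tail over a declared background.  Preranked GSEA
computes the classic weighted running-sum enrichment score over a ranked
gene list with a gene-label permutation null for p-values and NES.  The
concordance helper reports Pearson and Spearman correlation between two
paired expression vectors (e.g., qRT-PCR vs RNA-seq estimates of the same
transcripts).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

logger = logging.getLogger("nashtx")


@dataclass
class GeneSetCollection:
    """Named gene sets (name -> member list) with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)


def hypergeometric_ora(
    query: set[str], sets: GeneSetCollection, background: set[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per set.

    P(X >= k) with N = |background|, K = |set ∩ background|, n = |query|,
    k = |set ∩ query|; BH q across the tested sets.  Sets disjoint from the
    background are skipped with a warning.
    """
    if not background:
        raise ValueError("background is empty")
    if not query:
        raise ValueError("query is empty")
    extra = set(query) - set(background)
    if extra:
        raise ValueError(f"query genes outside background: {sorted(extra)[:5]}")
    rows = []
    N, n = len(background), len(query)
    for name, genes in sets.sets.items():
        inset = set(genes) & background
        if not inset:
            logger.warning("ORA: set %s disjoint from background; skipped", name)
            continue
        K = len(inset)
        k = len(inset & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "n_set": K, "n_overlap": k, "p_value": p})
    out = pd.DataFrame(rows, columns=["set", "n_set", "n_overlap", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"]) if len(out) else []
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def _running_es(in_set: np.ndarray, scores: np.ndarray, weight: float) -> float:
    """Signed maximum deviation of the GSEA running sum."""
    w = np.abs(scores) ** weight
    nr = w[in_set].sum()
    n_miss = (~in_set).sum()
    if n_miss == 0:
        raise ValueError("set covers the entire ranked list; ES undefined")
    if nr == 0:  # all in-set scores zero under weight>0: fall back to equal hits
        step_hit = np.where(in_set, 1.0 / in_set.sum(), 0.0)
    else:
        step_hit = np.where(in_set, w / nr, 0.0)
    steps = step_hit - np.where(~in_set, 1.0 / n_miss, 0.0)
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked`` maps unique gene ids to scores sorted in descending order.
    ES is the maximum signed running-sum deviation (hits weighted by
    |score|^weight, misses by 1/(N-K)); NES divides ES by the mean |ES| of
    same-sign permutations; the permutation p uses the (1+b)/(1+m)
    estimator.  Sets smaller than ``min_size`` after intersection with the
    ranked list are skipped with a warning.
    """
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    if (np.diff(scores) > 0).any():
        raise ValueError("scores must be sorted in descending order")
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)

    rows = []
    for name, members in sets.sets.items():
        hit_pos = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        K = len(hit_pos)
        if K == N:
            raise ValueError(f"set {name!r} covers the entire ranked list; "
                             "ES undefined (no misses)")
        if K < min_size:
            logger.warning(
                "GSEA: set %s skipped (%d usable genes of %d ranked)", name, K, N
            )
            continue
        in_set = np.zeros(N, dtype=bool)
        in_set[hit_pos] = True
        es = _running_es(in_set, scores, weight)

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            mask = np.zeros(N, dtype=bool)
            mask[rng.choice(N, size=K, replace=False)] = True
            perm_es[b] = _running_es(mask, scores, weight)
        same = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same):
            p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + len(same))
            nes = es / np.abs(same).mean()
        else:
            p, nes = 1.0 / (1.0 + n_perm), np.nan
        rows.append(
            {"set": name, "n_overlap": K, "es": es, "nes": nes,
             "p_value": float(p), "n_perm_used": int(len(same))}
        )
    out = pd.DataFrame(
        rows, columns=["set", "n_overlap", "es", "nes", "p_value", "n_perm_used"]
    )
    out["q_value"] = bh_fdr(out["p_value"]) if len(out) else []
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def concordance(x, y) -> dict:
    """Pearson and Spearman correlation between paired expression vectors.

    Vectors are used as given (log2-transform upstream when comparing
    platforms on the log scale).  Raises on zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input vector")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }
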