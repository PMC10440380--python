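"""Synthetic bulk and single-cell data with known ground truth.

The bulk generator emulates the study design: female and male knockout mice
on a low-fat (LFD) or western diet (WD) sampled at 1 and 40 weeks, with 4
LFD and 8 WD animals per sex per timepoint.  Counts are negative binomial
around log2-additive group means; diet main effects shift both WD groups,
while interaction effects shift only the WD-40wk cell (a diet effect that
emerges with feeding duration).  The single-cell generator plants disjoint
cell-type-unique marker genes: low baseline everywhere, ``marker_fold`` x
baseline in the owning type only.

Every generator is a pure function of its config (including the seed).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DIETS, SEXES, TIMES, CountMatrix, DesignTable

logger = logging.getLogger("nashtx")

TRUTH_COLUMNS = [
    "gene_id", "is_de_1wk", "is_de_40wk", "is_interaction",
    "true_log2fc_1wk", "true_log2fc_40wk", "origin_cell_type",
]


@dataclass
class BulkSimConfig:
    """Parameters of the bulk count simulation.

    Group sizes are per diet x time x sex cell, matching the emulated
    feeding trial's 4
    LFD / 8 WD animals per sex per timepoint.
    """

    n_genes: int = 2000
    n_per_group_lfd: int = 4
    n_per_group_wd: int = 8
    frac_de_main: float = 0.10
    frac_interaction: float = 0.10
    effect_log2_main: float = 1.0
    effect_log2_interaction: float = 2.0
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    nb_dispersion: float = 0.1
    library_size_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group_lfd <= 0 or self.n_per_group_wd <= 0:
            raise ValueError("dimensions must be positive")
        for f in (self.frac_de_main, self.frac_interaction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.frac_de_main + self.frac_interaction > 1.0:
            raise ValueError("frac_de_main + frac_interaction must not exceed 1")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ValueError("baseline_log2_mean_range must be (low, high)")


@dataclass
class ScSimConfig:
    """Parameters of the single-cell UMI simulation.

    ``marker_baseline_umi`` is the expected library-size-normalized UMI of a
    planted marker outside its own type (at ``scale_factor`` per cell); it is
    kept below typical marker-calling floors so the planted markers really
    are cell-type-unique.
    """

    n_cell_types: int = 4
    cells_per_type: int = 150
    n_genes: int = 1500
    markers_per_type: int = 20
    marker_fold: float = 8.0
    library_size_mean: float = 5000.0
    nb_dispersion: float = 0.2
    marker_baseline_umi: float = 0.4
    scale_factor: float = 10000.0
    library_size_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "cells_per_type", "n_genes", "markers_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("markers_per_type x n_cell_types must not exceed n_genes")
        if self.marker_fold < 1.0:
            raise ValueError("marker_fold must be >= 1")
        if self.library_size_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("library size and dispersion must be positive")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with mean mu and variance mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_bulk_counts(
    config: BulkSimConfig,
    *,
    gene_ids: list[str] | None = None,
    forced_interaction: list[str] | None = None,
    origin_map: dict[str, str] | None = None,
) -> tuple[CountMatrix, DesignTable, pd.DataFrame]:
    """Simulate the 2x2x2 bulk design; returns (counts, design, truth ledger).

    ``forced_interaction`` (gene ids) reserves those genes as interaction
    genes before random allocation — used when linking the bulk effects to
    markers planted in a single-cell simulation.  ``origin_map`` fills the
    truth ledger's ``origin_cell_type`` column.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(cfg.n_genes)
    if len(genes) != cfg.n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    # samples: time-major, then diet, sex, replicate
    rows = []
    for time in TIMES:
        for diet in DIETS:
            n = cfg.n_per_group_lfd if diet == "LFD" else cfg.n_per_group_wd
            for sex in SEXES:
                for i in range(n):
                    rows.append(
                        {"sample_id": f"{diet}_{time}wk_{sex}{i + 1}",
                         "diet": diet, "time": time, "sex": sex}
                    )
    design = DesignTable(pd.DataFrame(rows))
    n_samples = len(rows)

    n_main = round(cfg.frac_de_main * cfg.n_genes)
    n_int = round(cfg.frac_interaction * cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    forced = [gene_index[g] for g in (forced_interaction or [])]
    if len(forced) > n_int:
        raise ValueError("more forced interaction genes than frac_interaction allows")
    remaining = np.setdiff1d(np.arange(cfg.n_genes), np.asarray(forced, dtype=int))
    perm = rng.permutation(remaining)
    int_idx = np.concatenate([np.asarray(forced, dtype=int), perm[: n_int - len(forced)]])
    main_idx = perm[n_int - len(forced): n_int - len(forced) + n_main]

    baseline = rng.uniform(*cfg.baseline_log2_mean_range, size=cfg.n_genes)
    main_sign = rng.choice([-1.0, 1.0], size=n_main)

    # per-gene log2 shift in each diet x time cell; order LFD1, WD1, LFD40, WD40
    shift = np.zeros((cfg.n_genes, 4))
    shift[main_idx, 1] = main_sign * cfg.effect_log2_main
    shift[main_idx, 3] = main_sign * cfg.effect_log2_main
    # interaction: WD effect emerges at 40 wk only (upregulation with duration)
    shift[int_idx, 3] += cfg.effect_log2_interaction

    cell_of_sample = np.array(
        [2 * (t == 40) + (d == "WD") for d, t in zip(design.table["diet"], design.table["time"])]
    )
    lib = rng.lognormal(mean=0.0, sigma=cfg.library_size_log_sd, size=n_samples)
    mu = 2.0 ** (baseline[:, None] + shift[:, cell_of_sample]) * lib[None, :]
    counts = _nb_draw(rng, mu, cfg.nb_dispersion)

    fc1 = shift[:, 1] - shift[:, 0]
    fc40 = shift[:, 3] - shift[:, 2]
    origin = [
        (origin_map or {}).get(g, "none") for g in genes
    ]
    is_int = np.zeros(cfg.n_genes, dtype=bool)
    is_int[int_idx] = True
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_de_1wk": fc1 != 0.0,
            "is_de_40wk": fc40 != 0.0,
            "is_interaction": is_int,
            "true_log2fc_1wk": fc1,
            "true_log2fc_40wk": fc40,
            "origin_cell_type": origin,
        }
    )
    cm = CountMatrix(counts, genes, design.sample_ids, role="bulk")
    return cm, design, truth


def simulate_sc_umis(
    config: ScSimConfig,
) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """Simulate a clustered cell x gene UMI matrix with planted unique markers.

    Returns (counts, true cell-type labels indexed by cell id, truth ledger
    with each gene's ``origin_cell_type``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    types = [f"type{i + 1}" for i in range(cfg.n_cell_types)]

    # baseline expected normalized-UMI profile (sums ~ scale_factor)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    base *= cfg.scale_factor / base.sum()

    perm = rng.permutation(cfg.n_genes)
    marker_idx = {
        t: np.sort(perm[i * cfg.markers_per_type:(i + 1) * cfg.markers_per_type])
        for i, t in enumerate(types)
    }
    all_markers = np.concatenate([marker_idx[t] for t in types])
    if len(np.unique(all_markers)) != len(all_markers):
        raise ValueError("marker allocation overlaps across types")
    base[all_markers] = cfg.marker_baseline_umi

    profiles = {}
    for t in types:
        prof = base.copy()
        prof[marker_idx[t]] *= cfg.marker_fold
        profiles[t] = prof / prof.sum()

    n_cells = cfg.n_cell_types * cfg.cells_per_type
    cell_ids, labels = [], []
    counts = np.empty((n_cells, cfg.n_genes), dtype=np.int64)
    row = 0
    for t in types:
        prof = profiles[t]
        lib = rng.lognormal(
            mean=np.log(cfg.library_size_mean), sigma=cfg.library_size_log_sd,
            size=cfg.cells_per_type,
        )
        mu = lib[:, None] * prof[None, :]
        counts[row: row + cfg.cells_per_type] = _nb_draw(rng, mu, cfg.nb_dispersion)
        for i in range(cfg.cells_per_type):
            cell_ids.append(f"{t}_c{i + 1}")
            labels.append(t)
        row += cfg.cells_per_type

    origin = np.array(["none"] * cfg.n_genes, dtype=object)
    for t in types:
        origin[marker_idx[t]] = t
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_de_1wk": False,
            "is_de_40wk": False,
            "is_interaction": False,
            "true_log2fc_1wk": 0.0,
            "true_log2fc_40wk": 0.0,
            "origin_cell_type": origin,
        }
    )
    cm = CountMatrix(counts, cell_ids, genes, role="sc")
    label_series = pd.Series(labels, index=cell_ids, name="cell_type")
    return cm, label_series, truth


def simulate_linked(
    bulk_config: BulkSimConfig, sc_config: ScSimConfig
) -> dict:
    """Simulate matched bulk and single-cell data over one gene universe.

    The single-cell simulation runs first; its planted markers become
    (a prefix of the) bulk interaction genes, and the bulk truth ledger's
    ``origin_cell_type`` records which cell type each such gene came from.
    Requires the two configs to agree on ``n_genes``.
    """
    if bulk_config.n_genes != sc_config.n_genes:
        raise ValueError("bulk and sc configs must share n_genes")
    sc_counts, sc_labels, sc_truth = simulate_sc_umis(sc_config)
    origin_map = {
        g: t for g, t in zip(sc_truth["gene_id"], sc_truth["origin_cell_type"])
        if t != "none"
    }
    n_int = round(bulk_config.frac_interaction * bulk_config.n_genes)
    forced = list(origin_map)[:n_int]
    bulk_counts, design, bulk_truth = simulate_bulk_counts(
        bulk_config,
        gene_ids=list(sc_counts.gene_ids),
        forced_interaction=forced,
        origin_map={g: origin_map[g] for g in forced},
    )
    return {
        "bulk_counts": bulk_counts,
        "design": design,
        "bulk_truth": bulk_truth,
        "sc_counts": sc_counts,
        "sc_labels": sc_labels,
        "sc_truth": sc_truth,
    }


def write_fixture_bundle(
    dir_path: str | Path,
    bulk: tuple[CountMatrix, DesignTable, pd.DataFrame] | None = None,
    sc: tuple[CountMatrix, pd.Series, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write simulated data as the plain-text bundle the readers consume.

    Bulk: counts TSV, design TSV, truth TSV.  Single cell: MTX triplet
    (matrix + gene/barcode sidecars), labels TSV, truth TSV.
    """
    from . import io as nio  # local import to avoid a cycle at module load

    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if bulk is not None:
        cm, design, truth = bulk
        written["bulk_counts"] = nio.write_counts_tsv(out / "bulk_counts.tsv", cm)
        written["design"] = nio.write_design(out / "design.tsv", design)
        written["bulk_truth"] = nio.write_table(out / "bulk_truth.tsv", truth)
    if sc is not None:
        cm, labels, truth = sc
        written.update(nio.write_sc_mtx(out, cm))
        lab = labels.rename_axis("cell_id").reset_index()
        written["sc_labels"] = nio.write_table(out / "sc_labels.tsv", lab)
        written["sc_truth"] = nio.write_table(out / "sc_truth.tsv", truth)
    logger.info("fixture bundle written to %s (%d files)", out, len(written))
    return written
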