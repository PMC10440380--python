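"""End-to-end orchestration: normalize -> DE -> overlap -> interaction ->
cluster/summarize -> (markers -> assignment) -> (ORA / GSEA), with a run
manifest recording configuration, versions and per-stage row counts.

Identical config + inputs reproduce identical stage outputs byte for byte
(the manifest's timestamp aside)."""
from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assign as assign_mod
from . import clusters as cl
from . import de
from . import enrich
from . import io as nio
from . import scmarkers as scm
from .config import PipelineConfig

logger = logging.getLogger("nashtx")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages the config's inputs support; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "versions": _versions(),
        "stages": {},
        "started": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, status: str, **info):
        manifest["stages"][stage] = {"status": status, **info}
        logger.info("stage %-12s %s %s", stage, status, info or "")

    if config.counts is None or config.design is None:
        raise StageError("normalize", ValueError("counts and design paths required"))

    # --- bulk side ----------------------------------------------------
    try:
        counts = nio.read_counts(config.counts, format="tsv")
        design = nio.read_design(config.design)
        missing = set(design.sample_ids) - set(counts.sample_ids)
        if missing:
            raise ValueError(f"design samples absent from counts: {sorted(missing)[:5]}")
        norm = de.quantile_normalize(counts)
        log2 = de.log2_transform(norm, config.pseudocount)
        nio.write_table(out / "normalized.tsv", norm.to_frame().rename_axis("gene_id"),
                        index=True)
        record("normalize", "complete", n_genes=norm.shape[0], n_samples=norm.shape[1])
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage-named abort
        raise StageError("normalize", e) from e

    de_tables = {}
    for time in (1, 40):
        stage = f"de_{time}wk"
        try:
            tab = de.de_per_timepoint(
                log2, design, time, fc_up=config.fc_up, fc_down=config.fc_down,
                fdr_max=config.fdr_max, pseudocount=config.pseudocount,
            )
            de_tables[time] = tab
            nio.write_table(out / f"de_{time}wk.tsv", tab, index=True)
            record(stage, "complete", n_genes=len(tab),
                   n_called=int((tab["call"] != "ns").sum()))
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    try:
        overlap = de.overlap_sets(de_tables[1], de_tables[40])
        nio.write_table(out / "overlap.tsv", overlap.to_frame())
        record("overlap", "complete", n_common=overlap.n_common)
    except Exception as e:  # noqa: BLE001
        raise StageError("overlap", e) from e

    try:
        inter = de.interaction_test(log2, design)
        nio.write_table(out / "interaction.tsv", inter, index=True)
        sig = inter.index[inter["q_value"] <= config.interaction_fdr].tolist()
        record("interaction", "complete", n_genes=len(inter), n_significant=len(sig))
    except Exception as e:  # noqa: BLE001
        raise StageError("interaction", e) from e

    try:
        means = cl.group_geometric_means(norm, design, config.pseudocount)
        sig_means = means.loc[sig] if len(sig) >= config.k else means
        clustering = cl.kmeans_cluster(
            sig_means, k=config.k, seed=config.seed, standardize=config.standardize
        )
        summary = cl.summarize_clusters(sig_means, clustering, stat=config.cluster_stat)
        nio.write_table(out / "group_means.tsv", means, index=True)
        nio.write_table(out / "clusters.tsv",
                        clustering.labels.rename_axis("gene_id"), index=True)
        nio.write_table(out / "cluster_summary.tsv", summary, index=True)
        record("cluster", "complete", n_genes=len(clustering.labels), k=config.k,
               inertia=clustering.inertia)
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", e) from e

    # --- single-cell side --------------------------------------------
    catalog = None
    if config.sc_matrix is not None:
        try:
            sc_counts = nio.read_counts(config.sc_matrix, format="mtx")
            sc_counts = scm.filter_sc(sc_counts, min_genes_per_cell=200,
                                      min_cells_per_gene=3)
            sc_expr = scm.normalize_umis(sc_counts)
            if config.sc_labels is not None:
                labels = nio.read_labels(config.sc_labels).reindex(sc_expr.cell_ids)
                if labels.isna().any():
                    raise ValueError("provided labels do not cover all retained cells")
            else:
                labels = scm.cluster_cells(
                    sc_expr, method=config.sc_cluster_method,
                    resolution_or_k=config.sc_resolution_or_k, seed=config.seed,
                )
            catalog = scm.derive_markers(
                sc_expr, labels, umi_min=config.umi_min,
                min_log2fc=config.min_log2fc, q_max=config.q_max,
                unique=config.unique_markers,
            )
            nio.write_table(out / "markers.tsv", catalog.table)
            record("markers", "complete", n_markers=len(catalog.table),
                   n_types=len(catalog.cell_types))
        except Exception as e:  # noqa: BLE001
            raise StageError("markers", e) from e

        try:
            assignment = assign_mod.assign_genes(
                sig, catalog, sc_universe=set(sc_expr.gene_ids),
                provenance=str(config.sc_matrix),
            )
            summary_a = assign_mod.assignment_summary(
                assignment, denominator=config.denominator
            )
            nio.write_table(out / "assignments.tsv", assignment.table)
            nio.write_table(out / "assignment_summary.tsv", summary_a)
            record("assign", "complete", n_queried=len(sig),
                   n_assigned=int((assignment.table["cell_type"] != "unassigned").sum()))
        except Exception as e:  # noqa: BLE001
            raise StageError("assign", e) from e
    else:
        record("markers", "skipped", reason="no sc inputs")
        record("assign", "skipped", reason="no sc inputs")

    # --- enrichment ---------------------------------------------------
    if config.gmt is not None:
        try:
            collection = nio.read_gmt(config.gmt)
            background = set(inter.index)
            query = set(sig) & background
            ora = enrich.hypergeometric_ora(query, collection, background) if query \
                else pd.DataFrame(columns=["set", "n_set", "n_overlap", "p_value", "q_value"])
            nio.write_table(out / "ora.tsv", ora)
            ranked = de_tables[40]["log2fc"].sort_values(ascending=False, kind="stable")
            gsea = enrich.gsea_preranked(
                ranked, collection, n_perm=config.n_perm, seed=config.seed
            )
            nio.write_table(out / "gsea.tsv", gsea)
            record("enrich", "complete", n_sets=len(collection),
                   n_ora_tested=len(ora), n_gsea_tested=len(gsea))
        except Exception as e:  # noqa: BLE001
            raise StageError("enrich", e) from e
    else:
        record("enrich", "skipped", reason="no GMT collection")

    manifest["finished"] = _time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8"
    )
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "nashtx": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
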