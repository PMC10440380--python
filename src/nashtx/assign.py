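"""Bulk-gene-to-cell-type assignment via marker-catalog membership.

A bulk gene is assigned to the cell type whose marker set contains it;
genes in no marker set are ``unassigned``.  Genes that were never measured
in the single-cell data can be flagged separately (reason ``not_measured``)
so they are not silently conflated with measured-but-unspecific genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MarkerCatalog

logger = logging.getLogger("nashtx")


@dataclass
class CellTypeAssignment:
    """gene_id -> (cell type or 'unassigned', reason), with catalog provenance."""

    table: pd.DataFrame  # columns: gene_id, cell_type, reason
    provenance: str = ""

    def type_of(self, gene: str) -> str:
        row = self.table.loc[self.table["gene_id"] == gene, "cell_type"]
        if row.empty:
            raise KeyError(gene)
        return row.iloc[0]


def assign_genes(
    genes: list[str],
    catalog: MarkerCatalog,
    sc_universe: set[str] | None = None,
    provenance: str = "",
) -> CellTypeAssignment:
    """Map each queried gene to its owning cell type.

    With a unique catalog every marker gene has exactly one owner.  For a
    non-unique catalog ties are resolved by highest log2 fold change vs the
    rest, then lexicographic cell-type name (logged).  When ``sc_universe``
    is given, queried genes outside it are reported ``unassigned`` with
    reason ``not_measured``.
    """
    if catalog.table.empty:
        raise ValueError("marker catalog is empty")
    cat = catalog.table
    owner: dict[str, str] = {}
    if catalog.unique:
        owner = dict(zip(cat["gene_id"], cat["cell_type"]))
    else:
        n_ties = 0
        for g, grp in cat.groupby("gene_id"):
            if len(grp) > 1:
                n_ties += 1
                grp = grp.sort_values(
                    ["log2fc", "cell_type"], ascending=[False, True], kind="stable"
                )
            owner[g] = grp["cell_type"].iloc[0]
        if n_ties:
            logger.info("assign_genes: %d gene(s) resolved by tie-break policy", n_ties)

    rows = []
    for g in genes:
        if sc_universe is not None and g not in sc_universe:
            rows.append({"gene_id": g, "cell_type": "unassigned", "reason": "not_measured"})
        elif g in owner:
            rows.append({"gene_id": g, "cell_type": owner[g], "reason": "marker"})
        else:
            rows.append({"gene_id": g, "cell_type": "unassigned", "reason": "no_marker"})
    table = pd.DataFrame(rows, columns=["gene_id", "cell_type", "reason"])
    if table["gene_id"].duplicated().any():
        raise ValueError("queried gene list contains duplicates")
    return CellTypeAssignment(table=table, provenance=provenance)


def assignment_summary(
    assignment: CellTypeAssignment, denominator: str = "queried"
) -> pd.DataFrame:
    """Counts and percentages of genes per cell type.

    ``denominator='queried'`` divides by all queried genes (the bar-plot
    convention); ``'assigned'`` divides by assigned genes only.
    Rows are ordered by descending count; an ``unassigned`` row is always
    present (0% under the 'assigned' denominator).
    """
    if denominator not in ("queried", "assigned"):
        raise ValueError("denominator must be 'queried' or 'assigned'")
    t = assignment.table
    if t.empty:
        raise ValueError("empty assignment")
    counts = t["cell_type"].value_counts()
    n_unassigned = int(counts.get("unassigned", 0))
    assigned = counts.drop("unassigned", errors="ignore")
    denom = len(t) if denominator == "queried" else int(assigned.sum())

    rows = [
        {"cell_type": ct, "n_genes": int(n),
         "pct": 100.0 * n / denom if denom else np.nan}
        for ct, n in assigned.sort_values(ascending=False).items()
    ]
    rows.append(
        {"cell_type": "unassigned", "n_genes": n_unassigned,
         "pct": (100.0 * n_unassigned / denom) if denominator == "queried" and denom
         else (0.0 if denom else np.nan)}
    )
    out = pd.DataFrame(rows, columns=["cell_type", "n_genes", "pct"])
    assert int(out["n_genes"].sum()) == len(t), "summary must conserve gene counts"
    return out
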