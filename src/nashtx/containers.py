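"""Shared in-memory containers for the bulk and single-cell pipeline.

The bulk side of the study is a 2x2x2 design: diet (low-fat vs western),
feeding duration (1 vs 40 weeks) and sex.  Downstream statistics pool the
sexes as replicates within each diet x time group, so the canonical group
labels are the four diet-time combinations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("nashtx")

DIETS = ("LFD", "WD")
TIMES = (1, 40)
SEXES = ("F", "M")
#: canonical diet x time group labels, in time-major order
GROUP_ORDER = ("LFD-1wk", "WD-1wk", "LFD-40wk", "WD-40wk")


def group_label(diet: str, time: int) -> str:
    return f"{diet}-{time}wk"


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class CountMatrix:
    """Non-negative integer count matrix with row/column identifiers.

    ``role`` declares the orientation: ``"bulk"`` matrices are gene x sample,
    ``"sc"`` matrices are cell x gene (the single-cell UMI convention).
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    role: str = "bulk"  # "bulk" (gene x sample) or "sc" (cell x gene)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )
        if self.role not in ("bulk", "sc"):
            raise ValueError(f"unknown role {self.role!r}")
        if not np.issubdtype(self.values.dtype, np.integer):
            as_int = self.values.astype(np.int64)
            if not np.array_equal(as_int, self.values):
                raise ValueError("counts must be integers")
            self.values = as_int
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")
        _check_unique(self.row_ids, "row ids")
        _check_unique(self.col_ids, "column ids")

    # orientation-aware accessors -------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return self.row_ids if self.role == "bulk" else self.col_ids

    @property
    def sample_ids(self) -> list[str]:
        if self.role != "bulk":
            raise AttributeError("sample_ids only defined for bulk matrices")
        return self.col_ids

    @property
    def cell_ids(self) -> list[str]:
        if self.role != "sc":
            raise AttributeError("cell_ids only defined for sc matrices")
        return self.row_ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class DesignTable:
    """Per-sample factors of the bulk design (diet, time, sex)."""

    table: pd.DataFrame  # columns: sample_id, diet, time, sex

    def __post_init__(self) -> None:
        required = ["sample_id", "diet", "time", "sex"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        t = self.table.copy()
        t["time"] = t["time"].astype(int)
        for col, levels in (("diet", DIETS), ("time", TIMES), ("sex", SEXES)):
            bad = set(t[col]) - set(levels)
            if bad:
                raise ValueError(
                    f"unknown {col} level(s) {sorted(bad)}; allowed: {list(levels)}"
                )
        _check_unique(t["sample_id"], "sample ids")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, diet: str | None = None, time: int | None = None,
                    sex: str | None = None) -> list[str]:
        m = pd.Series(True, index=self.table.index)
        if diet is not None:
            m &= self.table["diet"] == diet
        if time is not None:
            m &= self.table["time"] == int(time)
        if sex is not None:
            m &= self.table["sex"] == sex
        return list(self.table.loc[m, "sample_id"])

    def group_of(self) -> pd.Series:
        """Diet x time group label per sample (sexes pooled)."""
        lab = [group_label(d, t) for d, t in zip(self.table["diet"], self.table["time"])]
        return pd.Series(lab, index=self.table["sample_id"].values, name="group")


@dataclass
class ExprMatrix:
    """Bulk gene x sample expression matrix with an explicit scale tag.

    ``scale`` is ``"normalized"`` (quantile-normalized counts scale) or
    ``"log2"`` (log2 of normalized + pseudocount).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape does not match id vectors")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale not in ("normalized", "log2"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ScExprMatrix:
    """Cell x gene matrix of library-size normalized UMIs."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    library_sizes: np.ndarray
    scale: str = "norm_umi"  # counts-per-`scale_factor` per cell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("sc expression matrix shape does not match id vectors")
        if (self.values < 0).any():
            raise ValueError("normalized UMIs must be non-negative")
        if len(self.library_sizes) != len(self.cell_ids):
            raise ValueError("one library size per cell required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MarkerCatalog:
    """Per-cell-type marker genes with supporting statistics.

    ``table`` columns: cell_type, gene_id, mean_norm_umi, log2fc, q_value.
    When ``unique`` is set each gene appears under at most one cell type.
    """

    table: pd.DataFrame
    unique: bool = True
    umi_min: float = 1.0

    def __post_init__(self) -> None:
        required = ["cell_type", "gene_id", "mean_norm_umi", "log2fc", "q_value"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker catalog missing columns: {missing}")
        if self.unique and self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"unique catalog contains duplicated genes: {list(dup)[:5]}")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    def genes_of(self, cell_type: str) -> list[str]:
        return list(self.table.loc[self.table["cell_type"] == cell_type, "gene_id"])


@dataclass
class OverlapSummary:
    """Bookkeeping of per-timepoint DE calls and their overlap."""

    n_total_1wk: int
    n_up_1wk: int
    n_down_1wk: int
    n_total_40wk: int
    n_up_40wk: int
    n_down_40wk: int
    n_common: int
    common_genes: list[str] = field(default_factory=list)
    n_universe: int = 0

    def __post_init__(self) -> None:
        if self.n_total_1wk != self.n_up_1wk + self.n_down_1wk:
            raise ValueError("1wk totals do not add up")
        if self.n_total_40wk != self.n_up_40wk + self.n_down_40wk:
            raise ValueError("40wk totals do not add up")
        if self.n_common > min(self.n_total_1wk, self.n_total_40wk):
            raise ValueError("overlap exceeds a marginal total")

    @property
    def pct_1wk(self) -> float:
        """DE calls at 1 wk as a percent of the tested transcript universe."""
        return 100.0 * self.n_total_1wk / self.n_universe if self.n_universe else float("nan")

    @property
    def pct_40wk(self) -> float:
        return 100.0 * self.n_total_40wk / self.n_universe if self.n_universe else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_total_1wk", "n_up_1wk", "n_down_1wk",
                    "n_total_40wk", "n_up_40wk", "n_down_40wk",
                    "n_common", "n_universe", "pct_1wk", "pct_40wk",
                ],
                "value": [
                    self.n_total_1wk, self.n_up_1wk, self.n_down_1wk,
                    self.n_total_40wk, self.n_up_40wk, self.n_down_40wk,
                    self.n_common, self.n_universe,
                    self.pct_1wk, self.pct_40wk,
                ],
            }
        )
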