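"""Readers and writers for the plain-text interchange formats.

TSV dialect: tab-delimited, UTF-8, mandatory header row, '.' decimal, no
quoting; floats round-trip through repr.  Counts travel either as a TSV
(genes as rows, first column ``gene_id``) or as a MatrixMarket triplet with
gene/barcode sidecar files.  Gene identifiers are opaque strings.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sparse

from .containers import CountMatrix, DesignTable
from .enrich import GeneSetCollection

logger = logging.getLogger("nashtx")

MTX_NAME = "matrix.mtx"
GENES_NAME = "genes.tsv"
BARCODES_NAME = "barcodes.tsv"


# ------------------------------------------------------------------- writers

def write_table(path: str | Path, frame: pd.DataFrame, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=index, float_format=None)
    return path


def write_counts_tsv(path: str | Path, counts: CountMatrix) -> Path:
    """Genes-as-rows TSV with a leading gene_id column (bulk orientation)."""
    frame = counts.to_frame()
    frame.index.name = "gene_id" if counts.role == "bulk" else "cell_id"
    return write_table(path, frame, index=True)


def write_design(path: str | Path, design: DesignTable) -> Path:
    return write_table(path, design.table)


def write_sc_mtx(dir_path: str | Path, counts: CountMatrix) -> dict[str, Path]:
    """MatrixMarket triplet: matrix.mtx (cell x gene) + gene/barcode sidecars."""
    if counts.role != "sc":
        raise ValueError("write_sc_mtx expects a cell x gene matrix")
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    mtx = out / MTX_NAME
    spio.mmwrite(str(mtx), sparse.coo_matrix(counts.values))
    genes = out / GENES_NAME
    genes.write_text("".join(f"{g}\n" for g in counts.gene_ids), encoding="utf-8")
    barcodes = out / BARCODES_NAME
    barcodes.write_text("".join(f"{c}\n" for c in counts.cell_ids), encoding="utf-8")
    return {"sc_matrix": mtx, "sc_genes": genes, "sc_barcodes": barcodes}


# ------------------------------------------------------------------- readers

def read_counts(
    path: str | Path, format: str = "tsv", orientation: str = "genes-by-samples"
) -> CountMatrix:
    """Read a count matrix.

    ``format='tsv'``: ``path`` is the TSV file; orientation declares whether
    rows are genes (bulk, default) or cells (``'cells-by-genes'``).
    ``format='mtx'``: ``path`` is the directory holding matrix.mtx with
    genes.tsv / barcodes.tsv sidecars; the matrix is cell x gene.
    """
    if format == "tsv":
        return _read_counts_tsv(Path(path), orientation)
    if format == "mtx":
        return read_sc_mtx(Path(path))
    raise ValueError("format must be 'tsv' or 'mtx'")


def _read_counts_tsv(path: Path, orientation: str) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()]
        raise ValueError(f"duplicate row id(s) in {path.name}: {sorted(set(dup))[:5]}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric entries in {path.name}")
    if (values < 0).any():
        raise ValueError(f"negative counts in {path.name}")
    if not np.array_equal(values, values.astype(np.int64)):
        raise ValueError(f"non-integer counts in {path.name}")
    role = "bulk" if orientation == "genes-by-samples" else "sc"
    return CountMatrix(values.astype(np.int64), list(frame.index.astype(str)),
                       list(frame.columns.astype(str)), role=role)


def read_sc_mtx(dir_path: str | Path) -> CountMatrix:
    """Read the MTX triplet written by :func:`write_sc_mtx` (cell x gene)."""
    d = Path(dir_path)
    mtx, genes_f, bc_f = d / MTX_NAME, d / GENES_NAME, d / BARCODES_NAME
    for f in (mtx, genes_f, bc_f):
        if not f.exists():
            raise FileNotFoundError(f"required sidecar missing: {f}")
    mat = spio.mmread(str(mtx))
    values = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    genes = genes_f.read_text(encoding="utf-8").split()
    cells = bc_f.read_text(encoding="utf-8").split()
    if values.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {values.shape} does not match "
            f"{len(cells)} barcodes x {len(genes)} genes"
        )
    if not np.array_equal(values, values.astype(np.int64)):
        raise ValueError("non-integer UMI counts in matrix.mtx")
    return CountMatrix(values.astype(np.int64), cells, genes, role="sc")


def read_design(path: str | Path) -> DesignTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return DesignTable(frame)


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (cell_id, cell_type) -> label Series."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("labels TSV needs two columns (cell_id, label)")
    return pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].values,
                     name="cell_type")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < len([g for g in genes if g]):
                logger.warning("GMT set %s: duplicate genes de-duplicated", name)
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path
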