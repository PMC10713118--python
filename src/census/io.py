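"""Readers and writers for count matrices, labels and annotation outputs.

Supported input formats:

* 10x-style MTX directories: ``matrix.mtx`` plus ``features.tsv`` (or
  ``genes.tsv``) and ``barcodes.tsv``, each optionally gzipped. The matrix
  is stored genes x cells and transposed on read.
* Dense CSV/TSV tables with row and column identifiers, either orientation
  (``cells_by_genes`` flag).

Labels are a TSV with a ``cell_id`` and a ``label`` column (or a single
label column aligned with the matrix's cell order).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, LabeledReference

__all__ = [
    "read_counts",
    "read_mtx_dir",
    "read_dense",
    "read_labels",
    "write_mtx_dir",
]


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(dirpath: Path, stems) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dirpath / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {stems} (plain or .gz) found in {dirpath}"
    )


def read_mtx_dir(path) -> CountMatrix:
    """Read a 10x-style MTX directory (genes x cells on disk)."""
    path = Path(path)
    mtx_path = _find(path, ["matrix.mtx"])
    with (gzip.open(mtx_path, "rb") if mtx_path.suffix == ".gz" else open(mtx_path, "rb")) as fh:
        mat = scipy.io.mmread(fh)
    feat_path = _find(path, ["features.tsv", "genes.tsv"])
    with _open_maybe_gz(feat_path) as fh:
        features = pd.read_csv(fh, sep="\t", header=None)
    bc_path = _find(path, ["barcodes.tsv"])
    with _open_maybe_gz(bc_path) as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None)
    gene_ids = features.iloc[:, 0].astype(str).values
    cell_ids = barcodes.iloc[:, 0].astype(str).values
    counts = sp.csr_matrix(mat).T  # to cells x genes
    return CountMatrix(counts, gene_ids, cell_ids)


def read_dense(path, *, cells_by_genes: bool = True, sep: str | None = None) -> CountMatrix:
    """Read a dense CSV/TSV count table with row/column identifiers."""
    path = Path(path)
    if sep is None:
        sep = "\t" if ".tsv" in path.name else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not cells_by_genes:
        df = df.T
    return CountMatrix(
        sp.csr_matrix(df.values.astype(np.float64)),
        gene_ids=df.columns.astype(str).values,
        cell_ids=df.index.astype(str).values,
    )


def read_counts(path, *, fmt: str | None = None, cells_by_genes: bool = True) -> CountMatrix:
    """Read counts from an MTX directory or a dense CSV/TSV file.

    ``fmt`` may be ``"mtx"`` or ``"csv"``; inferred from the path when
    omitted (a directory implies MTX).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.is_dir() else "csv"
    if fmt == "mtx":
        return read_mtx_dir(path)
    if fmt in ("csv", "tsv"):
        return read_dense(path, cells_by_genes=cells_by_genes)
    raise ValueError(f"unknown counts format {fmt!r}")


def read_labels(path, cell_ids=None) -> np.ndarray:
    """Read per-cell labels from TSV/CSV.

    With ``cell_id``/``label`` columns, labels are aligned to ``cell_ids``;
    a single-column file is taken in matrix order.
    """
    path = Path(path)
    sep = "\t" if ".tsv" in path.name else ","
    df = pd.read_csv(path, sep=sep)
    if "terminal_label" in df.columns and "label" not in df.columns:
        df = df.rename(columns={"terminal_label": "label"})
    if {"cell_id", "label"} <= set(df.columns):
        if cell_ids is not None:
            series = df.set_index("cell_id")["label"]
            missing = [c for c in cell_ids if c not in series.index]
            if missing:
                raise ValueError(
                    f"labels file {path} lacks labels for {len(missing)} cells "
                    f"(first: {missing[:3]})"
                )
            return series.loc[list(cell_ids)].astype(str).values.astype(object)
        return df["label"].astype(str).values.astype(object)
    if "label" in df.columns:
        return df["label"].astype(str).values.astype(object)
    return df.iloc[:, -1].astype(str).values.astype(object)


def write_mtx_dir(cm: CountMatrix, path) -> None:
    """Write a CountMatrix as a 10x-style MTX directory (genes x cells)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(cm.counts.T))
    pd.DataFrame({"gene": cm.gene_ids}).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": cm.cell_ids}).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_labeled_reference(counts_path, labels_path, **kwargs) -> LabeledReference:
    cm = read_counts(counts_path, **kwargs)
    labels = read_labels(labels_path, cell_ids=cm.cell_ids)
    return LabeledReference(matrix=cm, labels=labels)
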