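"""Core data containers: raw count matrices and labeled references.

All downstream stages consume :class:`CountMatrix` (sparse cells x genes raw
counts with gene/cell identifiers) or :class:`LabeledReference` (a count
matrix plus one cell-type label per cell). Validation is strict at
construction time so later stages can assume clean inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "LabeledReference", "MIN_CELLS_PER_TYPE"]

#: Below this many cells per cell type, classifier performance degrades
#: noticeably; references with rarer types trigger a warning, not an error.
MIN_CELLS_PER_TYPE = 20


def _as_csr(counts) -> sp.csr_matrix:
    if sp.issparse(counts):
        mat = counts.tocsr().astype(np.float64)
    else:
        mat = sp.csr_matrix(np.asarray(counts, dtype=np.float64))
    return mat


@dataclass
class CountMatrix:
    """Sparse cells x genes matrix of raw (nonnegative integer) counts.

    Parameters
    ----------
    counts
        Any scipy sparse matrix or dense array-like, cells in rows.
    gene_ids
        Unique gene identifiers, one per column.
    cell_ids
        Unique cell barcodes, one per row.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    _gene_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {n_genes} columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids has {len(self.cell_ids)} entries for {n_cells} rows"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids contain duplicates")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_indices(self, genes) -> np.ndarray:
        """Column indices of ``genes``; -1 for genes absent from this matrix."""
        return np.array([self._gene_index.get(g, -1) for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(self.counts[idx], self.gene_ids, self.cell_ids[idx])

    def dense_submatrix(self, genes) -> np.ndarray:
        """Dense cells x len(genes) block; columns for absent genes are NaN."""
        idx = self.gene_indices(genes)
        out = np.full((self.n_cells, len(idx)), np.nan)
        present = idx >= 0
        if present.any():
            out[:, present] = self.counts[:, idx[present]].toarray()
        return out

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


@dataclass
class LabeledReference:
    """A count matrix with one cell-type label per cell."""

    matrix: CountMatrix
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.matrix.n_cells:
            raise ValueError(
                f"{len(self.labels)} labels for {self.matrix.n_cells} cells"
            )
        counts = pd.Series(self.labels).value_counts()
        empty = counts[counts == 0]
        if len(empty):
            raise ValueError(f"cell types with zero cells: {sorted(empty.index)}")
        rare = counts[counts < MIN_CELLS_PER_TYPE]
        if len(rare):
            warnings.warn(
                "cell types with fewer than "
                f"{MIN_CELLS_PER_TYPE} cells (expect degraded models): "
                f"{dict(rare)}",
                stacklevel=2,
            )

    @property
    def cell_types(self) -> list:
        return sorted(set(self.labels))

    def cells_of_type(self, label) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def subset_cells(self, idx) -> "LabeledReference":
        idx = np.asarray(idx)
        return LabeledReference(self.matrix.subset_cells(idx), self.labels[idx])
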