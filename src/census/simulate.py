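"""Synthetic scRNA-seq generator with known hierarchical cell-type structure.

Counts are negative-binomial with multiplicative marker effects: the
cell-type tree is built over the requested labels (balanced recursive
bisection of the label list), each branch of the tree owns a disjoint block
of marker genes upregulated by ``effect_size``-fold in every cell type
under that branch, and per-cell library sizes are log-normal. Dropout is
independent per-entry Bernoulli zeroing, which exercises the
zeros-become-missing pathway downstream. Everything is reproducible under
the spec's seed.

The default configuration emulates a small pancreas-style dataset: four
immune types (T, NK, B, macrophage) against four non-immune types (ductal,
acinar, fibroblast, endothelial), with the immune/non-immune split at the
root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix, LabeledReference
from .hierarchy import CellTypeHierarchy, _renumber

__all__ = ["GeneratorSpec", "generate", "make_tumor", "apply_monotone_distortion"]

DEFAULT_LABELS = (
    "T cell",
    "NK cell",
    "B cell",
    "macrophage",
    "ductal",
    "acinar",
    "fibroblast",
    "endothelial",
)


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic generator.

    ``labels`` fixes both the cell types and the ground-truth tree: the tree
    is the balanced binary bisection of the label tuple in order, so
    adjacent labels are siblings.
    """

    labels: tuple = DEFAULT_LABELS
    n_cells_per_type: int = 200
    n_genes: int = 2000
    markers_per_branch: int = 25
    effect_size: float = 4.0  # fold-change of branch markers
    baseline_mean: float = 1.0  # negative-binomial mean of background genes
    dispersion: float = 8.0  # negative-binomial size parameter
    dropout_rate: float = 0.2
    libsize_sigma: float = 0.3  # per-cell log-normal library-size spread
    distortion_exponent: float | None = None  # optional monotone batch warp
    seed: int = 0

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("need at least 2 cell types")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        n_branches = 2 * (len(self.labels) - 1)
        if self.markers_per_branch * n_branches > self.n_genes:
            raise ValueError(
                f"{n_branches} branches x {self.markers_per_branch} markers "
                f"exceed {self.n_genes} genes"
            )
        for name in ("dropout_rate",):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.effect_size <= 0 or self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("effect_size, baseline_mean, dispersion must be > 0")


def _balanced_tree(labels) -> CellTypeHierarchy:
    """Balanced binary tree over ``labels`` in order (adjacent = siblings)."""
    children: dict = {}
    leaf_labels: dict = {}
    counter = [0]

    def build(chunk):
        counter[0] += 1
        nid = counter[0]
        if len(chunk) == 1:
            leaf_labels[nid] = chunk[0]
        else:
            half = (len(chunk) + 1) // 2
            a = build(chunk[:half])
            b = build(chunk[half:])
            children[nid] = (a, b)
        return nid

    build(list(labels))
    return _renumber(CellTypeHierarchy(children=children, leaf_labels=leaf_labels))


def _branch_marker_map(tree: CellTypeHierarchy, spec: GeneratorSpec) -> dict:
    """Assign a disjoint marker-gene block to every branch (child node)."""
    marker_map: dict = {}
    cursor = 0
    for node in tree.internal_nodes:
        for child in tree.children[node]:
            genes = list(range(cursor, cursor + spec.markers_per_branch))
            marker_map[child] = genes
            cursor += spec.markers_per_branch
    return marker_map


def _type_means(tree: CellTypeHierarchy, spec: GeneratorSpec) -> dict:
    """Per-type expected expression vector (before library-size scaling)."""
    marker_map = _branch_marker_map(tree, spec)
    means = {}
    for label in tree.labels:
        mu = np.full(spec.n_genes, spec.baseline_mean)
        for node in tree.lineage(label)[1:]:  # every branch the lineage enters
            mu[marker_map[node]] *= spec.effect_size
        means[label] = mu
    return means


def _nb_draw(rng, mu: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def generate(spec: GeneratorSpec):
    """Draw a labeled reference from the generator.

    Returns ``(ref, tree, marker_map)`` where ``tree`` is the ground-truth
    hierarchy and ``marker_map`` maps each branch's child node id to the
    gene-index block upregulated under it. Byte-identical under the same
    spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    tree = _balanced_tree(spec.labels)
    marker_map = _branch_marker_map(tree, spec)
    means = _type_means(tree, spec)
    rows = []
    labels = []
    for label in spec.labels:  # declared order, not tree order
        mu = means[label]
        lib = rng.lognormal(mean=0.0, sigma=spec.libsize_sigma, size=spec.n_cells_per_type)
        block = _nb_draw(rng, lib[:, None] * mu[None, :], spec.dispersion)
        if spec.dropout_rate > 0:
            keep = rng.random(block.shape) >= spec.dropout_rate
            block = block * keep
        rows.append(block)
        labels.extend([label] * spec.n_cells_per_type)
    counts = np.vstack(rows).astype(np.float64)
    if spec.distortion_exponent is not None:
        counts = counts**spec.distortion_exponent
    gene_ids = np.array([f"gene_{i:05d}" for i in range(spec.n_genes)], dtype=object)
    cell_ids = np.array([f"cell_{i:06d}" for i in range(counts.shape[0])], dtype=object)
    ref = LabeledReference(
        matrix=CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids),
        labels=np.array(labels, dtype=object),
    )
    return ref, tree, marker_map


def make_tumor(
    ref: LabeledReference,
    source_label: str,
    *,
    n_cells: int = 300,
    n_tumor_markers: int = 50,
    effect_size: float = 8.0,
    baseline_mean: float = 1.0,
    dispersion: float = 8.0,
    dropout_rate: float = 0.2,
    tumor_genes=None,
    replace: bool | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Synthesize malignant cells derived from one reference cell type.

    Copies of source-type cells receive an added exclusive "malignancy"
    marker block while keeping their original branch markers, so the base
    model still routes them to the source leaf and the cell of origin is
    recoverable. With ``effect_size`` at 1x baseline the tumor gains no
    distinguishing signal (a null tumor).

    ``tumor_genes`` defaults to the last ``n_tumor_markers`` genes of the
    matrix, which the generator leaves as background genes.

    Source cells are sampled without replacement whenever enough are
    available (``replace=None``). Duplicated rows concentrate spurious
    variance and visibly distort PCA/UMAP embeddings, so tumor cells meant
    to be embedded alongside their source dataset should always come from
    distinct source cells (and, ideally, from cells not themselves in the
    query).
    """
    if source_label not in set(ref.labels):
        raise ValueError(f"source type {source_label!r} not present in reference")
    rng = np.random.default_rng(seed)
    src = ref.cells_of_type(source_label)
    if replace is None:
        replace = len(src) < n_cells
    pick = rng.choice(src, size=n_cells, replace=replace)
    counts = np.asarray(ref.matrix.counts[pick].todense(), dtype=np.float64)
    if tumor_genes is None:
        tumor_idx = np.arange(ref.matrix.n_genes - n_tumor_markers, ref.matrix.n_genes)
    else:
        tumor_idx = ref.matrix.gene_indices(tumor_genes)
        if (tumor_idx < 0).any():
            raise ValueError("tumor_genes contains genes absent from the reference")
    mu = baseline_mean * effect_size
    block = _nb_draw(rng, np.full((n_cells, len(tumor_idx)), mu), dispersion)
    if dropout_rate > 0:
        keep = rng.random(block.shape) >= dropout_rate
        block = block * keep
    counts[:, tumor_idx] = np.maximum(counts[:, tumor_idx], block)
    cell_ids = np.array([f"tumor_{i:05d}" for i in range(n_cells)], dtype=object)
    return CountMatrix(sp.csr_matrix(counts), ref.matrix.gene_ids, cell_ids)


def apply_monotone_distortion(
    cm: CountMatrix, *, scale=None, exponent: float = 1.0, seed: int = 0
) -> CountMatrix:
    """Per-cell library scaling plus a strictly increasing count warp.

    Both transforms preserve each cell's within-cell count ordering (and
    zeros), so percentile-rank features — and hence node predictions — are
    unchanged. Used to emulate batch/depth differences.
    """
    X = np.asarray(cm.counts.todense(), dtype=np.float64)
    if scale is None:
        rng = np.random.default_rng(seed)
        scale = rng.uniform(0.2, 5.0, size=cm.n_cells)
    X = X * np.asarray(scale)[:, None]
    if exponent != 1.0:
        if exponent <= 0:
            raise ValueError("exponent must be positive to stay monotone")
        X = X**exponent
    return CountMatrix(sp.csr_matrix(X), cm.gene_ids, cm.cell_ids)
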