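"""Query annotation: embedding, fine clustering, and label stabilization.

Cells are annotated by walking the hierarchy from the root: each node's
booster predicts which child every cell routed to that node belongs to, and
a label-stabilizing step then pools information across the query's own 2D
structure to correct isolated prediction errors before descending.

Stabilization alternates two moves on a fixed 2D embedding of the query:

1. within each fine (shared-nearest-neighbor) cluster, every cell takes the
   cluster's most common label;
2. a per-label density contour (2D Gaussian KDE at the level enclosing 95%
   of that label's cells) is drawn; a fine cluster situated completely
   within exactly one *other* label's contour region — and entirely outside
   its own label's region — is a mislabeled island and takes the enclosing
   contour's label, while cells inside two or more contours take the most
   common label among cells of that same overlap region.

The island rule is applied per cluster, not per cell: a label's contour
always excludes a small fraction of that label's own outlying cells, and
flipping those individually would steadily erode small populations that are
in fact correctly labeled. The moves repeat until no contours overlap or no
label changes, with an iteration cap. Stabilization never invents a label
absent from its input and is idempotent at its fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import gaussian_kde

from .config import RunConfig, derive_seed
from .containers import CountMatrix
from .training import CensusModel

__all__ = [
    "EmbeddingClusters",
    "AnnotationResult",
    "embed_query",
    "cluster_embedding",
    "embed_and_cluster",
    "stabilize_labels",
    "annotate",
]

# below ~25 points a 2D normal-reference KDE is too unstable to define a
# meaningful contour; labels with fewer cells contribute no contour
MIN_CELLS_FOR_CONTOUR = 25


@dataclass
class EmbeddingClusters:
    """A fixed 2D embedding of the query plus a fine clustering of it."""

    coords: np.ndarray  # cells x 2
    fine_cluster: np.ndarray  # one cluster id per cell

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.fine_cluster = np.asarray(self.fine_cluster)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be cells x 2")
        if len(self.fine_cluster) != len(self.coords):
            raise ValueError("one fine cluster id required per cell")

    @property
    def n_cells(self) -> int:
        return len(self.coords)

    def subset(self, idx) -> "EmbeddingClusters":
        idx = np.asarray(idx)
        return EmbeddingClusters(self.coords[idx], self.fine_cluster[idx])


def embed_query(query: CountMatrix, config: RunConfig | None = None) -> np.ndarray:
    """Standard 2D embedding: TP10K -> log1p -> (HVG) -> (scale) -> PCA -> UMAP.

    Variable-gene subsetting and unit-variance scaling are available via the
    config but off by default: on gene panels where most genes are
    uninformative, equalizing per-gene variance drowns the discriminative
    axes, and dispersion-based variable-gene selection is unreliable.
    """
    import scanpy as sc

    config = config or RunConfig()
    if query.n_cells < 3:
        raise ValueError("need at least 3 cells to embed")
    adata = query.to_anndata()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    if config.n_top_genes is not None and config.n_top_genes < query.n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=config.n_top_genes)
        adata = adata[:, adata.var["highly_variable"]].copy()
    if config.scale:
        sc.pp.scale(adata, max_value=10)
    n_pcs = int(min(config.n_pcs, adata.n_vars - 1, adata.n_obs - 1))
    sc.tl.pca(adata, n_comps=n_pcs, random_state=derive_seed(config.seed, "pca"))
    n_neighbors = config.n_neighbors
    if n_neighbors >= query.n_cells:
        n_neighbors = max(2, query.n_cells - 1)
        warnings.warn(
            f"n_neighbors reduced to {n_neighbors} for {query.n_cells} cells",
            stacklevel=2,
        )
    sc.pp.neighbors(
        adata,
        n_neighbors=n_neighbors,
        n_pcs=n_pcs,
        random_state=derive_seed(config.seed, "umap"),
    )
    sc.tl.umap(
        adata,
        min_dist=config.min_dist,
        random_state=derive_seed(config.seed, "umap"),
    )
    return np.asarray(adata.obsm["X_umap"], dtype=np.float64)


def cluster_embedding(
    coords: np.ndarray,
    config: RunConfig | None = None,
    *,
    n_types_hint: int = 1,
) -> np.ndarray:
    """Fine SNN/Leiden clustering of a 2D embedding.

    The clustering resolution is raised until the cluster count reaches
    roughly ``cluster_factor`` times the expected number of final cell
    types (floor ``min_clusters``), exploiting the embedding's preservation
    of local structure while avoiding co-clustering of distant cells.
    """
    import scanpy as sc
    from anndata import AnnData

    config = config or RunConfig()
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    target = min(max(config.min_clusters, config.cluster_factor * n_types_hint), n)
    adata = AnnData(X=coords.copy())
    adata.obsm["X_embed"] = coords
    nn = min(15, max(2, n - 1))
    sc.pp.neighbors(
        adata,
        use_rep="X_embed",
        n_neighbors=nn,
        random_state=derive_seed(config.seed, "snn"),
    )
    resolution = 2.0
    labels = None
    for _ in range(8):
        sc.tl.leiden(
            adata,
            resolution=resolution,
            key_added="fine",
            flavor="igraph",
            n_iterations=2,
            directed=False,
            random_state=derive_seed(config.seed, "leiden"),
        )
        labels = adata.obs["fine"].astype(str).values
        if len(np.unique(labels)) >= target:
            break
        resolution *= 2.0
    return np.asarray(labels)


def embed_and_cluster(
    query: CountMatrix,
    config: RunConfig | None = None,
    *,
    n_types_hint: int = 1,
    coords: np.ndarray | None = None,
) -> EmbeddingClusters:
    """Embed the query in 2D (unless ``coords`` is given) and finely cluster it."""
    config = config or RunConfig()
    if coords is None:
        coords = embed_query(query, config)
    fine = cluster_embedding(coords, config, n_types_hint=n_types_hint)
    return EmbeddingClusters(coords=coords, fine_cluster=fine)


# ---------------------------------------------------------------------------
# label stabilization
# ---------------------------------------------------------------------------

def _modal(values) -> object:
    """Most common value; ties break to the smallest (deterministic)."""
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    return vals[np.argmax(counts)]  # np.unique sorts, argmax takes first max


def _propagate_cluster_modes(labels: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    out = labels.copy()
    for c in np.unique(clusters):
        mask = clusters == c
        out[mask] = _modal(labels[mask])
    return out


def _contour_membership(
    coords: np.ndarray, labels: np.ndarray, config: RunConfig
) -> tuple[np.ndarray, list]:
    """Boolean cells x labels membership matrix of per-label density regions.

    Each label's density is a Gaussian KDE of its cells evaluated on a
    ``grid_size``-squared grid spanning the embedding plus a 5% margin and
    interpolated back to cell positions; the contour level is the density
    value enclosing ``contour_mass`` of that label's own cells. Labels with
    too few cells or degenerate geometry contribute no contour.
    """
    uniq = sorted(np.unique(labels))
    n = len(coords)
    inside = np.zeros((n, len(uniq)), dtype=bool)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    lo = lo - 0.05 * span
    hi = hi + 0.05 * span
    gx = np.linspace(lo[0], hi[0], config.grid_size)
    gy = np.linspace(lo[1], hi[1], config.grid_size)
    mesh = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    for j, lab in enumerate(uniq):
        pts = coords[labels == lab]
        if len(pts) < MIN_CELLS_FOR_CONTOUR:
            continue
        try:
            kde = gaussian_kde(pts.T)
            dens_grid = kde(mesh.T).reshape(config.grid_size, config.grid_size)
        except Exception:  # singular covariance: all cells collinear
            continue
        interp = RegularGridInterpolator(
            (gx, gy), dens_grid, bounds_error=False, fill_value=0.0
        )
        dens_cells = interp(coords)
        own = dens_cells[labels == lab]
        level = np.quantile(own, 1.0 - config.contour_mass)
        inside[:, j] = dens_cells >= max(level, 1e-300)
    return inside, uniq


@dataclass
class StabilizationResult:
    labels: np.ndarray
    converged: bool
    n_iter: int


def stabilize_labels(
    ec: EmbeddingClusters,
    labels,
    config: RunConfig | None = None,
) -> StabilizationResult:
    """Iteratively smooth per-cell labels over the 2D embedding.

    See the module docstring for the algorithm. Returns the stabilized
    labels together with a convergence flag; non-convergence within
    ``max_iter`` rounds returns the current labels with ``converged=False``.
    """
    config = config or RunConfig()
    labels = np.asarray(labels).copy()
    if len(labels) != ec.n_cells:
        raise ValueError("one label required per cell")
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        before = labels.copy()
        labels = _propagate_cluster_modes(labels, ec.fine_cluster)
        if len(np.unique(labels)) > 1:
            inside, uniq = _contour_membership(ec.coords, labels, config)
            lab_col = {lab: j for j, lab in enumerate(uniq)}
            n_in = inside.sum(axis=1)
            # mislabeled islands: a cluster wholly inside exactly one other
            # label's region and nowhere inside its own adopts that label
            for c in np.unique(ec.fine_cluster):
                m = ec.fine_cluster == c
                cur = labels[np.flatnonzero(m)[0]]  # uniform after step 1
                j_cur = lab_col.get(cur)
                if j_cur is not None and inside[m, j_cur].any():
                    continue
                enclosing = [
                    j for lab, j in lab_col.items()
                    if lab != cur and inside[m, j].all()
                ]
                if len(enclosing) == 1:
                    labels[m] = uniq[enclosing[0]]
            # overlap regions: modal label per distinct overlap signature
            overlap = n_in >= 2
            has_overlap = bool(overlap.any())
            if has_overlap:
                sigs: dict = {}
                for i in np.flatnonzero(overlap):
                    sigs.setdefault(inside[i].tobytes(), []).append(i)
                for idx in sigs.values():
                    labels[np.asarray(idx)] = _modal(labels[np.asarray(idx)])
            labels = _propagate_cluster_modes(labels, ec.fine_cluster)
        else:
            has_overlap = False
        if not has_overlap or np.array_equal(labels, before):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"label stabilization did not converge in {config.max_iter} iterations",
            stacklevel=2,
        )
    return StabilizationResult(labels=labels, converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# hierarchical annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationResult:
    """Per-cell terminal labels plus the full per-node prediction history."""

    cell_ids: np.ndarray
    terminal_labels: np.ndarray
    history: list  # per cell: list of (node_id, predicted_child, probability)
    embedding: EmbeddingClusters
    node_assignments: dict = field(default_factory=dict)  # node -> cell idx array

    def to_frame(self) -> pd.DataFrame:
        import json as _json

        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "terminal_label": self.terminal_labels,
                "history": [
                    _json.dumps(
                        [
                            {"node": int(n), "child": int(c), "prob": round(float(p), 6)}
                            for n, c, p in h
                        ]
                    )
                    for h in self.history
                ],
                "terminal_prob": [h[-1][2] if h else np.nan for h in self.history],
            }
        )


def annotate(
    model: CensusModel,
    query: CountMatrix,
    config: RunConfig | None = None,
    *,
    embedding: EmbeddingClusters | None = None,
) -> AnnotationResult:
    """Annotate query cells by recursive node prediction with stabilization.

    The query is embedded and finely clustered once; then, walking internal
    nodes from the root, each node's booster predicts child assignments for
    the cells currently routed to it, stabilization smooths those
    assignments over the embedding, and cells descend to their children
    until every cell reaches a leaf.
    """
    config = config or model.config
    shared = set(model.gene_universe) & set(query.gene_ids)
    if not shared:
        raise ValueError(
            "empty gene intersection between model gene universe and query"
        )
    if embedding is None:
        embedding = embed_and_cluster(
            query, config, n_types_hint=model.hierarchy.n_leaves
        )
    h = model.hierarchy
    n = query.n_cells
    assignment = np.full(n, h.root, dtype=int)
    history: list = [[] for _ in range(n)]
    node_assignments: dict = {h.root: np.arange(n)}
    # BFS ids guarantee parents precede children, so ascending order is a
    # valid traversal
    for node in h.internal_nodes:
        S = np.flatnonzero(assignment == node)
        if S.size == 0:
            continue
        nm = model.node_models[node]
        child, prob, p2 = nm.predict(query.subset_cells(S))
        if config.stabilize and S.size >= 2:
            child = stabilize_labels(embedding.subset(S), child, config).labels
            second = child == nm.child_labels[1]
            prob = np.where(second, p2, 1.0 - p2)
        assignment[S] = child
        for k, cell in enumerate(S):
            history[cell].append((node, int(child[k]), float(prob[k])))
        for c in nm.child_labels:
            idx = S[child == c]
            if idx.size:
                node_assignments[c] = idx
    terminal = np.array([h.leaf_labels[a] for a in assignment], dtype=object)
    return AnnotationResult(
        cell_ids=query.cell_ids,
        terminal_labels=terminal,
        history=history,
        embedding=embedding,
        node_assignments=node_assignments,
    )
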