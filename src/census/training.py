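"""Model training: marker selection, feature transforms, per-node boosters.

One binary gradient-boosted tree classifier is trained per internal node of
the cell-type hierarchy. Before training, the count data is modified in
three ways:

1. zeros become missing values (NaN), handled natively by the booster's
   sparsity-aware split finding;
2. the remaining values in each cell are percentile ranked (average-rank
   ties, divided by the number of observed genes), which makes features
   invariant to any strictly monotone per-cell count distortion and thereby
   robust to sequencing-depth and batch differences;
3. a sparsified copy of the training data — a per-cell random 90% (by
   default) of genes forced to missing before ranking — is appended, which
   teaches the models to cope with much sparser query data.

Marker genes per node are chosen by a two-sided Wilcoxon rank-sum test on
per-cell TP10K + log1p expression between the node's two child populations,
keeping genes with adjusted p < 0.05 (Bonferroni over the gene universe).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xgboost as xgb
from scipy.stats import mannwhitneyu, rankdata
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .config import RunConfig, derive_seed
from .containers import CountMatrix, LabeledReference
from .hierarchy import (
    CellTypeHierarchy,
    aggregate_pseudobulk,
    build_hierarchy,
)

__all__ = [
    "MarkerTable",
    "NodeModel",
    "CensusModel",
    "transform_counts",
    "sparsify",
    "select_markers",
    "node_training_sets",
    "train_node_model",
    "train_census",
]

SERIAL_FORMAT = "census-model-v1"


# ---------------------------------------------------------------------------
# feature transforms
# ---------------------------------------------------------------------------

def transform_counts(X) -> np.ndarray:
    """Percentile-rank each row, treating zeros (and NaN) as missing.

    Observed values are replaced by ``rank / n_observed`` with average-rank
    ties, so outputs lie in (0, 1] and the maximum observed value per row is
    1 whenever at least one gene is observed. Missing entries stay NaN.
    Ranks are invariant to any strictly increasing transform of the counts.
    """
    X = np.array(X, dtype=np.float64, copy=True)
    if X.ndim == 1:
        return transform_counts(X[None, :])[0]
    X[X == 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        ranks = rankdata(X, method="average", axis=1, nan_policy="omit")
    n_obs = np.sum(~np.isnan(X), axis=1, keepdims=True).astype(np.float64)
    n_obs[n_obs == 0] = 1.0  # avoid 0/0; all-NaN rows stay all-NaN anyway
    return ranks / n_obs


def sparsify(X, fraction: float, seed: int) -> np.ndarray:
    """Force a random ``fraction`` of each row to missing, then rank.

    Per cell, ``floor(fraction * n_genes)`` entries chosen uniformly without
    replacement are set to missing before percentile ranking. Deterministic
    under ``seed``.
    """
    if not (0.0 <= fraction <= 0.99):
        raise ValueError(f"sparsify fraction must be in [0, 0.99], got {fraction}")
    X = np.array(X, dtype=np.float64, copy=True)
    n_cells, n_genes = X.shape
    k = int(np.floor(fraction * n_genes))
    rng = np.random.default_rng(seed)
    for i in range(n_cells):
        drop = rng.choice(n_genes, size=k, replace=False)
        X[i, drop] = np.nan
    return transform_counts(X)


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

@dataclass
class MarkerTable:
    """Significant marker genes for one binary split, ordered by adjusted p."""

    genes: list
    adjusted_p: np.ndarray
    raw_p: np.ndarray
    direction: np.ndarray  # +1 if up in group2 (child_labels[1]), -1 otherwise

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "adjusted_p": self.adjusted_p,
                "raw_p": self.raw_p,
                "direction": self.direction,
            }
        )


def _normalize_log(counts: sp.spmatrix) -> np.ndarray:
    """Per-cell TP10K then log1p, densified."""
    X = np.asarray(counts.todense(), dtype=np.float64)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(X / lib * 1e4)


def select_markers(
    group1: sp.spmatrix,
    group2: sp.spmatrix,
    gene_ids,
    *,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> MarkerTable:
    """Two-sided rank-sum marker test between two cell groups.

    Expression is per-cell TP10K + log1p normalized (marker choice only; the
    boosters themselves see percentile ranks). P-values are adjusted over
    the full gene universe; genes with adjusted p < ``alpha`` are returned
    ordered by adjusted then raw p.
    """
    if group1.shape[0] == 0 or group2.shape[0] == 0:
        raise ValueError("both groups must be non-empty for marker selection")
    gene_ids = np.asarray(gene_ids, dtype=object)
    X1 = _normalize_log(sp.csr_matrix(group1))
    X2 = _normalize_log(sp.csr_matrix(group2))
    # constant genes (identical values in both groups) carry no information;
    # mannwhitneyu's tie-corrected normal approximation divides by zero there
    combined = np.vstack([X1, X2])
    constant = np.ptp(combined, axis=0) == 0
    pvals = np.ones(len(gene_ids))
    if (~constant).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = mannwhitneyu(
                X1[:, ~constant], X2[:, ~constant], axis=0, alternative="two-sided"
            )
        p = np.asarray(res.pvalue, dtype=np.float64)
        p[np.isnan(p)] = 1.0
        pvals[~constant] = np.clip(p, 0.0, 1.0)
    method = {"bonferroni": "bonferroni", "fdr_bh": "fdr_bh"}[adjust]
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=method)
    keep = np.flatnonzero(p_adj < alpha)
    if keep.size == 0:
        raise ValueError(
            "no significant marker genes at adjusted "
            f"p < {alpha}; consider a looser threshold or a custom gene list"
        )
    order = keep[np.lexsort((pvals[keep], p_adj[keep]))]
    direction = np.where(X2[:, order].mean(axis=0) >= X1[:, order].mean(axis=0), 1, -1)
    return MarkerTable(
        genes=list(gene_ids[order]),
        adjusted_p=p_adj[order],
        raw_p=pvals[order],
        direction=direction,
    )


# ---------------------------------------------------------------------------
# per-node training
# ---------------------------------------------------------------------------

def node_training_sets(
    h: CellTypeHierarchy, ref: LabeledReference, node: int
) -> dict:
    """Cells routed through ``node``, grouped and relabeled by child node.

    Returns ``{child_node_id: cell index array}``; every reference cell whose
    leaf lineage passes through ``node`` appears in exactly one group.
    """
    if h.is_leaf(node):
        raise ValueError(f"node {node} is a leaf; only internal nodes have models")
    groups = {}
    for child in h.children[node]:
        types = set(h.leaves_under(child))
        idx = np.flatnonzero(pd.Series(ref.labels).isin(types).values)
        if idx.size == 0:
            raise ValueError(
                f"child node {child} of node {node} has no training cells "
                f"(types {sorted(types)})"
            )
        groups[child] = idx
    return groups


@dataclass
class NodeModel:
    """One trained binary classifier at one internal hierarchy node."""

    node_id: int
    child_labels: tuple  # (left child id, right child id)
    marker_genes: list
    booster: xgb.XGBClassifier
    training_auc: float
    markers: MarkerTable | None = field(default=None, repr=False)

    def predict(self, cells: CountMatrix):
        """Predict the child node for each cell.

        Cells are restricted to the node's marker genes; genes absent from
        the query and zero counts both become missing values. Returns
        ``(child_ids, probability_of_assigned_child)``. A probability tie at
        exactly 0.5 breaks deterministically to the first child.
        """
        X = transform_counts(cells.dense_submatrix(self.marker_genes))
        p2 = self.booster.predict_proba(X)[:, 1]  # P(child_labels[1])
        choose_second = p2 > 0.5  # tie -> first child
        child = np.where(choose_second, self.child_labels[1], self.child_labels[0])
        prob = np.where(choose_second, p2, 1.0 - p2)
        return child, prob, p2


class _RawBoosterClassifier:
    """predict_proba adapter around a deserialized raw xgboost Booster.

    Produces bit-identical probabilities to the original fitted classifier,
    so a saved and reloaded model predicts exactly like the one in memory.
    """

    def __init__(self, booster: xgb.Booster):
        self.raw = booster

    def predict_proba(self, X) -> np.ndarray:
        p = self.raw.predict(xgb.DMatrix(np.asarray(X), missing=np.nan))
        return np.column_stack([1.0 - p, p])


def save_booster(booster, path) -> None:
    """Serialize a fitted classifier (or raw-booster adapter) as JSON."""
    raw = booster.raw if isinstance(booster, _RawBoosterClassifier) else booster.get_booster()
    raw.save_model(str(path))


def load_booster(path) -> _RawBoosterClassifier:
    raw = xgb.Booster()
    raw.load_model(str(path))
    return _RawBoosterClassifier(raw)


def _make_booster(params: dict, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        **params,
        random_state=seed,
        missing=np.nan,
        objective="binary:logistic",
        eval_metric="logloss",
    )


def train_node_model(
    node: int,
    child_labels: tuple,
    X1_raw: np.ndarray,
    X2_raw: np.ndarray,
    marker_genes: list,
    config: RunConfig,
    markers: MarkerTable | None = None,
) -> NodeModel:
    """Train one node's booster on full + sparsified percentile-rank data.

    ``X1_raw``/``X2_raw`` are raw count blocks (cells x marker genes) for the
    two child populations, in ``marker_genes`` column order.
    """
    if len(marker_genes) == 0:
        raise ValueError("marker gene list must be non-empty")
    if X1_raw.shape[0] == 0 or X2_raw.shape[0] == 0:
        raise ValueError("both classes must be present to train a node model")
    Xraw = np.vstack([X1_raw, X2_raw])
    y = np.concatenate([np.zeros(X1_raw.shape[0]), np.ones(X2_raw.shape[0])])
    X_full = transform_counts(Xraw)
    X_sparse = sparsify(
        Xraw, config.sparsify_fraction, derive_seed(config.seed, f"sparsify-{node}")
    )
    X_train = np.vstack([X_full, X_sparse])
    y_train = np.concatenate([y, y])
    booster = _make_booster(
        config.booster_params, derive_seed(config.seed, f"booster-{node}")
    )
    booster.fit(X_train, y_train)
    scores = booster.predict_proba(X_train)[:, 1]
    auc = float(roc_auc_score(y_train, scores))
    return NodeModel(
        node_id=node,
        child_labels=tuple(child_labels),
        marker_genes=list(marker_genes),
        booster=booster,
        training_auc=auc,
        markers=markers,
    )


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

@dataclass
class CensusModel:
    """Cell-type hierarchy plus one trained model per internal node."""

    hierarchy: CellTypeHierarchy
    node_models: dict  # internal node id -> NodeModel
    gene_universe: np.ndarray
    config: RunConfig

    def __post_init__(self):
        missing = set(self.hierarchy.internal_nodes) - set(self.node_models)
        if missing:
            raise ValueError(f"internal nodes without models: {sorted(missing)}")

    @property
    def median_training_auc(self) -> float:
        return float(np.median([m.training_auc for m in self.node_models.values()]))

    def marker_frame(self) -> pd.DataFrame:
        """All node markers as one table (node_id, gene, adjusted_p, direction)."""
        frames = []
        for nid in sorted(self.node_models):
            m = self.node_models[nid]
            if m.markers is not None:
                f = m.markers.to_frame()
            else:
                f = pd.DataFrame({"gene": m.marker_genes})
            f.insert(0, "node_id", nid)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    # -- serialization: directory bundle -------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "hierarchy.json").write_text(self.hierarchy.to_json())
        (path / "hierarchy.nwk").write_text(self.to_newick())
        (path / "config.json").write_text(self.config.to_json())
        meta = {"format": SERIAL_FORMAT, "nodes": {}}
        for nid, m in self.node_models.items():
            save_booster(m.booster, path / f"node_{nid}.booster.json")
            meta["nodes"][str(nid)] = {
                "child_labels": list(m.child_labels),
                "marker_genes": list(m.marker_genes),
                "training_auc": m.training_auc,
            }
        meta["gene_universe"] = list(self.gene_universe)
        (path / "manifest.json").write_text(json.dumps(meta, indent=1))
        self.marker_frame().to_csv(path / "markers.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "CensusModel":
        path = Path(path)
        meta = json.loads((path / "manifest.json").read_text())
        if meta.get("format") != SERIAL_FORMAT:
            raise ValueError(f"unrecognized model bundle format: {meta.get('format')}")
        hierarchy = CellTypeHierarchy.from_json((path / "hierarchy.json").read_text())
        config = RunConfig.from_json((path / "config.json").read_text())
        node_models = {}
        for nid_s, info in meta["nodes"].items():
            nid = int(nid_s)
            booster = load_booster(path / f"node_{nid}.booster.json")
            node_models[nid] = NodeModel(
                node_id=nid,
                child_labels=tuple(info["child_labels"]),
                marker_genes=list(info["marker_genes"]),
                booster=booster,
                training_auc=float(info["training_auc"]),
            )
        return cls(
            hierarchy=hierarchy,
            node_models=node_models,
            gene_universe=np.asarray(meta["gene_universe"], dtype=object),
            config=config,
        )

    def to_newick(self) -> str:
        return self.hierarchy.to_newick()


def train_census(
    ref: LabeledReference,
    config: RunConfig | None = None,
    *,
    hierarchy: CellTypeHierarchy | None = None,
    marker_overrides: dict | None = None,
) -> CensusModel:
    """Train a full hierarchical model from a labeled reference.

    Builds the cell-type hierarchy from pseudo-bulk profiles (unless one is
    supplied), then for each internal node selects markers and trains a
    booster on the node's two child populations.

    Parameters
    ----------
    ref
        Labeled reference counts.
    config
        Training configuration; defaults are used when omitted.
    hierarchy
        Optional pre-built hierarchy whose leaves must match the reference's
        label set.
    marker_overrides
        Optional ``{node_id: [genes]}`` replacing the rank-sum selection at
        those nodes.
    """
    config = config or RunConfig()
    if hierarchy is None:
        hierarchy = build_hierarchy(aggregate_pseudobulk(ref))
    else:
        if set(hierarchy.labels) != set(ref.cell_types):
            raise ValueError("hierarchy leaves do not match reference labels")
    node_models = {}
    for node in hierarchy.internal_nodes:
        try:
            groups = node_training_sets(hierarchy, ref, node)
            (c1, idx1), (c2, idx2) = sorted(groups.items())
            overridden = marker_overrides.get(node) if marker_overrides else None
            if overridden is not None:
                genes = list(overridden)
                markers = None
            else:
                markers = select_markers(
                    ref.matrix.counts[idx1],
                    ref.matrix.counts[idx2],
                    ref.matrix.gene_ids,
                    alpha=config.marker_alpha,
                    adjust=config.marker_adjust,
                )
                genes = markers.genes
            gidx = ref.matrix.gene_indices(genes)
            X1 = np.asarray(ref.matrix.counts[idx1][:, gidx].todense(), dtype=float)
            X2 = np.asarray(ref.matrix.counts[idx2][:, gidx].todense(), dtype=float)
            node_models[node] = train_node_model(
                node, (c1, c2), X1, X2, genes, config, markers=markers
            )
        except ValueError as err:
            raise ValueError(f"training failed at node {node}: {err}") from err
    return CensusModel(
        hierarchy=hierarchy,
        node_models=node_models,
        gene_universe=np.asarray(ref.matrix.gene_ids, dtype=object),
        config=config,
    )
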