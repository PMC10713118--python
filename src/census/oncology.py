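"""Cancer cell detection and cell-of-origin inference.

A cancer model is a single binary node trained to distinguish malignant
cells (cell lines or tumor scRNA-seq) from organ-specific normal
epithelium, using the same marker-selection and data-modification pipeline
as any hierarchy node. At query time it is applied only to cells whose
terminal annotation is one of the model's declared normal epithelial
labels; for cells called cancer, the pre-existing terminal annotation is
retained as the predicted cell of origin (no additional model query), so
the call is consistent with the base prediction record by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from .annotation import AnnotationResult, EmbeddingClusters, stabilize_labels
from .config import RunConfig
from .containers import CountMatrix, LabeledReference
from .training import (
    SERIAL_FORMAT,
    NodeModel,
    load_booster,
    save_booster,
    select_markers,
    train_node_model,
)

__all__ = ["CancerModel", "train_cancer_model", "detect_cancer"]

NORMAL, CANCER = "normal", "cancer"


@dataclass
class CancerModel:
    """Binary malignant-vs-normal-epithelium classifier for one organ."""

    organ: str
    node: NodeModel  # child_labels == (NORMAL, CANCER)
    normal_epithelial_labels: frozenset

    @property
    def training_auc(self) -> float:
        return self.node.training_auc

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        save_booster(self.node.booster, path / "cancer.booster.json")
        manifest = {
            "format": SERIAL_FORMAT,
            "kind": "cancer",
            "organ": self.organ,
            "normal_epithelial_labels": sorted(self.normal_epithelial_labels),
            "marker_genes": list(self.node.marker_genes),
            "training_auc": self.node.training_auc,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "CancerModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest.get("kind") != "cancer":
            raise ValueError("not a cancer model bundle")
        booster = load_booster(path / "cancer.booster.json")
        node = NodeModel(
            node_id=0,
            child_labels=(NORMAL, CANCER),
            marker_genes=list(manifest["marker_genes"]),
            booster=booster,
            training_auc=float(manifest["training_auc"]),
        )
        return cls(
            organ=manifest["organ"],
            node=node,
            normal_epithelial_labels=frozenset(
                manifest["normal_epithelial_labels"]
            ),
        )


def train_cancer_model(
    cancer_cells: CountMatrix,
    normal_epithelium: LabeledReference,
    organ: str,
    config: RunConfig | None = None,
) -> CancerModel:
    """Train a malignant-vs-normal-epithelium model for one organ.

    ``normal_epithelium`` carries the base-hierarchy leaf labels that define
    the epithelial gate at prediction time (e.g. ductal, acinar, endocrine
    for pancreas). The malignant side may come from cell lines or tumors.
    """
    config = config or RunConfig()
    if cancer_cells.n_cells == 0 or normal_epithelium.matrix.n_cells == 0:
        raise ValueError("both cancer and normal classes must be non-empty")
    if not np.array_equal(cancer_cells.gene_ids, normal_epithelium.matrix.gene_ids):
        raise ValueError("cancer and normal matrices must share one gene universe")
    markers = select_markers(
        normal_epithelium.matrix.counts,
        cancer_cells.counts,
        cancer_cells.gene_ids,
        alpha=config.marker_alpha,
        adjust=config.marker_adjust,
    )
    gidx = cancer_cells.gene_indices(markers.genes)
    X_norm = np.asarray(
        normal_epithelium.matrix.counts[:, gidx].todense(), dtype=float
    )
    X_cancer = np.asarray(cancer_cells.counts[:, gidx].todense(), dtype=float)
    node = train_node_model(
        0, (NORMAL, CANCER), X_norm, X_cancer, markers.genes, config, markers=markers
    )
    return CancerModel(
        organ=organ,
        node=node,
        normal_epithelial_labels=frozenset(normal_epithelium.cell_types),
    )


def detect_cancer(
    base_result: AnnotationResult,
    cm: CancerModel,
    query: CountMatrix,
    ec: EmbeddingClusters | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Call malignancy on epithelial-annotated cells of an annotated query.

    Only cells whose terminal base annotation is in the model's normal
    epithelial label set are eligible; everything else is structurally
    excluded from malignancy calls. The binary cancer/normal call is
    stabilized over the same embedding used for base annotation. Returns a
    per-cell table with ``is_cancer``, ``cancer_probability`` and
    ``cell_of_origin`` (the retained base terminal label, for cancer cells).
    """
    config = config or RunConfig()
    ec = ec or base_result.embedding
    gate = np.flatnonzero(
        pd.Series(base_result.terminal_labels)
        .isin(cm.normal_epithelial_labels)
        .values
    )
    out = pd.DataFrame(
        {
            "cell_id": base_result.cell_ids,
            "terminal_label": base_result.terminal_labels,
            "is_cancer": False,
            "cancer_probability": np.nan,
            "cell_of_origin": pd.array([None] * len(base_result.cell_ids)),
        }
    )
    if gate.size == 0:
        warnings.warn("no cells passed the epithelial gate; empty call set")
        return out
    call, prob, p_cancer = cm.node.predict(query.subset_cells(gate))
    if config.stabilize and gate.size >= 2:
        call = stabilize_labels(ec.subset(gate), call, config).labels
    is_cancer = call == CANCER
    out.loc[gate, "is_cancer"] = is_cancer
    out.loc[gate, "cancer_probability"] = p_cancer
    origin = np.where(is_cancer, base_result.terminal_labels[gate], None)
    out.loc[gate, "cell_of_origin"] = origin
    return out
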