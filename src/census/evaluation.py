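"""Prediction-quality metrics: per-class F1, balanced accuracy, label similarity.

Metrics follow the one-vs-rest convention: each class observed in either
the true or predicted labels gets TP/FP/FN/TN counts and derived precision,
recall, F1 and balanced accuracy. F1 for a class with no true and no
predicted positives is undefined and reported as absent (NaN), not zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import multilabel_confusion_matrix

from .hierarchy import CellTypeHierarchy

__all__ = [
    "per_class_metrics",
    "macro_f1",
    "accuracy",
    "label_similarity_vector",
]


def per_class_metrics(true_labels, predicted_labels) -> pd.DataFrame:
    """One-vs-rest confusion counts and derived metrics per class.

    Balanced accuracy is (sensitivity + specificity) / 2. Undefined ratios
    (zero denominators) are NaN.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label vectors differ in length: {len(true_labels)} vs "
            f"{len(predicted_labels)}"
        )
    classes = sorted(set(true_labels) | set(predicted_labels))
    mcm = multilabel_confusion_matrix(true_labels, predicted_labels, labels=classes)
    rows = []
    for cls, cm in zip(classes, mcm):
        tn, fp, fn, tp = cm.ravel()
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
            f1 = np.nan if (tp + fp + fn == 0) else 0.0
        else:
            f1 = 2 * prec * rec / (prec + rec)
        ba = (rec + spec) / 2 if not (np.isnan(rec) or np.isnan(spec)) else np.nan
        rows.append(
            {
                "class": cls,
                "TP": int(tp),
                "FP": int(fp),
                "FN": int(fn),
                "TN": int(tn),
                "precision": prec,
                "recall": rec,
                "specificity": spec,
                "F1": f1,
                "balanced_accuracy": ba,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def macro_f1(true_labels, predicted_labels) -> float:
    """Mean per-class F1 over classes where F1 is defined."""
    table = per_class_metrics(true_labels, predicted_labels)
    return float(table["F1"].dropna().mean())


def accuracy(true_labels, predicted_labels) -> float:
    """Fraction of exact label matches (micro accuracy)."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    return float(np.mean(t == p))


def label_similarity_vector(
    h: CellTypeHierarchy, true_labels, predicted_labels
) -> np.ndarray:
    """Per-cell lineage-overlap score between true and predicted leaf labels.

    Each score is the number of shared root-side lineage nodes divided by
    the shorter lineage's length; 1 for an exact match (or when one label's
    lineage is a prefix of the other's), always > 0 since the root is shared.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    cache: dict = {}
    out = np.empty(len(true_labels))
    for i, (a, b) in enumerate(zip(true_labels, predicted_labels)):
        key = (a, b)
        if key not in cache:
            cache[key] = h.label_similarity(a, b)
        out[i] = cache[key]
    return out
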