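"""Scoring segmentations against ground truth.

The headline score is the normalized mutual information in the asymmetric
convention NMI = I(pred; truth) / H(truth): the mutual information of the
predicted assignment with the ground-truth labeling, divided by the entropy
of the ground truth.  Both are plug-in (maximum-likelihood) estimates from
the empirical contingency table; the log base cancels.  Unassigned points
(label 0) are excluded by default — their count is reported — or can be
treated as a class of their own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _entropy
from sklearn.metrics import mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .sampler import UNASSIGNED, FitResult

__all__ = ["LabelComparison", "nmi", "compare", "majority_map"]

logger = logging.getLogger(__name__)


@dataclass
class LabelComparison:
    contingency: np.ndarray  # predicted x true count table
    pred_classes: np.ndarray
    true_classes: np.ndarray
    nmi: float
    n_unassigned: int


def _apply_policy(pred, truth, unassigned_policy):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    n_unassigned = int(np.sum(pred == UNASSIGNED))
    if unassigned_policy == "exclude":
        keep = pred != UNASSIGNED
        return pred[keep], truth[keep], n_unassigned
    if unassigned_policy == "own_class":
        return pred, truth, n_unassigned
    raise ValueError(f"unknown unassigned_policy {unassigned_policy!r}")


def nmi(pred, truth, unassigned_policy: str = "exclude") -> float:
    """I(pred; truth) / H(truth) from the empirical contingency table.

    Degenerate cases: a constant ground truth has zero entropy, so the
    ratio is defined as 1 if the prediction is constant too and 0
    otherwise (with a warning); an empty comparison (everything unassigned
    under the exclude policy) is NaN with a warning.
    """
    pred, truth, _ = _apply_policy(pred, truth, unassigned_policy)
    if pred.size == 0:
        warnings.warn("no assigned points to score; NMI undefined", stacklevel=2)
        return float("nan")
    h_truth = _entropy(np.unique(truth, return_counts=True)[1])
    if h_truth == 0.0:
        warnings.warn("constant ground truth: NMI defined by convention", stacklevel=2)
        return 1.0 if np.unique(pred).size == 1 else 0.0
    return float(mutual_info_score(truth, pred) / h_truth)


def compare(
    fit: FitResult | np.ndarray,
    truth,
    unassigned_policy: str = "exclude",
) -> LabelComparison:
    """Contingency table + NMI for a fit result (or raw labels) vs truth."""
    pred_all = fit.labels if isinstance(fit, FitResult) else np.asarray(fit)
    pred, kept_truth, n_unassigned = _apply_policy(pred_all, truth, unassigned_policy)
    if pred.size == 0:
        warnings.warn("all points unassigned; empty comparison", stacklevel=2)
        return LabelComparison(
            contingency=np.zeros((0, 0), dtype=np.int64),
            pred_classes=np.asarray([]),
            true_classes=np.asarray([]),
            nmi=float("nan"),
            n_unassigned=n_unassigned,
        )
    table = contingency_matrix(pred, kept_truth)  # rows: pred, cols: true
    return LabelComparison(
        contingency=np.asarray(table),
        pred_classes=np.unique(pred),
        true_classes=np.unique(kept_truth),
        nmi=nmi(pred_all, truth, unassigned_policy),
        n_unassigned=n_unassigned,
    )


def majority_map(pred, truth, unassigned_policy: str = "exclude") -> dict:
    """Match each true component to the predicted manifold holding most of
    its points (majority overlap).  Returns {true_class: pred_class}."""
    comparison = compare(np.asarray(pred), truth, unassigned_policy)
    mapping = {}
    for j, true_class in enumerate(comparison.true_classes):
        i = int(np.argmax(comparison.contingency[:, j]))
        mapping[true_class] = comparison.pred_classes[i]
    return mapping
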