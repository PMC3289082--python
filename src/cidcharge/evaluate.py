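"""ROC/AUC evaluation against known charge labels.

The positive class is +3 throughout. Ties in the score are handled by the
rank-average (midpoint) convention, under which the trapezoidal area under
the ROC curve equals the two-sample rank statistic: the probability that a
random +3 spectrum outscores a random +2 spectrum, counting ties as one
half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import EXPECTED_DIRECTIONS, FeatureMatrix


@dataclass
class RocResult:
    """Ordered (FPR, TPR) points from (0,0) to (1,1) plus the AUC."""

    points: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, int, int]:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {2, 3}:
        raise ValueError("labels must be 2 or 3")
    n_pos = int((labels == 3).sum())
    n_neg = int((labels == 2).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both charge classes must be present to evaluate")
    return labels, n_pos, n_neg


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and trapezoidal AUC with +3 as the positive class.

    The threshold sweeps the unique score values from high to low; tied
    scores move along the curve in one step, so the trapezoidal area
    implements the midpoint tie convention exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels, n_pos, n_neg = _check_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    is_pos = (labels[order] == 3).astype(float)
    # cut after the last element of each tied block
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    cuts = np.concatenate([distinct, [scores.size - 1]])
    tp = np.cumsum(is_pos)[cuts]
    fp = np.cumsum(1.0 - is_pos)[cuts]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(points=np.column_stack([fpr, tpr]), auc=auc, n_pos=n_pos, n_neg=n_neg)


def per_feature_auc(matrix: FeatureMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Single-feature discriminant power, orientation-corrected.

    Each column is used alone as a score; the reported AUC is
    ``max(auc, 1 - auc)`` so a discriminant feature scores above 0.5
    whichever class it favors, with the orientation noted.
    """
    rows = []
    for name in matrix.feature_names:
        raw_auc = roc_auc(matrix.column(name), labels).auc
        rows.append(
            {
                "feature": name,
                "auc": max(raw_auc, 1.0 - raw_auc),
                "orientation": "+3_high" if raw_auc >= 0.5 else "+3_low",
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def class_mean_report(matrix: FeatureMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Per-class means of the scaled features with direction checks.

    The ``expected`` column states the physical direction ('>' means the
    +2 mean should exceed the +3 mean) and ``holds`` whether the data
    agree.
    """
    labels, _, _ = _check_labels(labels)
    rows = []
    for name in matrix.feature_names:
        col = matrix.column(name)
        mean2 = float(col[labels == 2].mean())
        mean3 = float(col[labels == 3].mean())
        expected = EXPECTED_DIRECTIONS[name]
        holds = mean2 > mean3 if expected == ">" else mean2 < mean3
        rows.append(
            {"feature": name, "mean_plus2": mean2, "mean_plus3": mean3,
             "expected": f"+2 {expected} +3", "holds": bool(holds)}
        )
    return pd.DataFrame(rows).set_index("feature")


def classification_summary(predicted: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Per-class precision and overall accuracy at the decision threshold."""
    predicted = np.asarray(predicted, dtype=int)
    labels, _, _ = _check_labels(labels)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and true labels must have equal length")
    out: dict[str, float] = {}
    for charge in (2, 3):
        called = predicted == charge
        out[f"precision_plus{charge}"] = (
            float((labels[called] == charge).mean()) if called.any() else float("nan")
        )
    out["accuracy"] = float((predicted == labels).mean())
    return out
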