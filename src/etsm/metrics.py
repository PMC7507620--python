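"""Validation metrics: rank-based AUC, sensitivity, F1 and average precision.

AUC is computed in its Mann-Whitney rank form

    AUC = (sum of positive-sample ranks - M(M+1)/2) / (M * N)

with ascending mid-ranks for tied scores, which equals the probability that a
random positive outscores a random negative, counting ties as half.
Sensitivity, precision and F1 classify at a fixed probability threshold
(default 0.5).  Average precision is the step-wise area under the
precision-recall curve, sum_k (R_k - R_{k-1}) P_k over descending-score
thresholds, with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError

__all__ = [
    "ScoredPredictions",
    "auc",
    "sensitivity",
    "precision",
    "f1",
    "average_precision",
    "compute_all",
    "METRIC_NAMES",
]

METRIC_NAMES = ("auc", "sensitivity", "f1", "average_precision")


@dataclass(frozen=True)
class ScoredPredictions:
    """Validation-set scores: true labels and predicted positive-class
    probabilities, classified at ``threshold``."""

    y_true: np.ndarray
    scores: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        y = np.asarray(self.y_true).astype(bool)
        s = np.asarray(self.scores, dtype=float)
        if y.shape != s.shape:
            raise ValueError("y_true and scores must have identical shape")
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        object.__setattr__(self, "y_true", y)
        object.__setattr__(self, "scores", s)

    @property
    def y_pred(self) -> np.ndarray:
        return self.scores >= self.threshold

    def _require_both_classes(self) -> None:
        if self.y_true.all() or not self.y_true.any():
            raise UndefinedMetricError(
                "metric undefined: validation set contains a single class"
            )


def auc(preds: ScoredPredictions) -> float:
    """Rank-form AUC with mid-rank tie handling."""
    preds._require_both_classes()
    ranks = rankdata(preds.scores)  # ascending mid-ranks
    m = int(preds.y_true.sum())
    n = len(preds.y_true) - m
    return float((ranks[preds.y_true].sum() - m * (m + 1) / 2) / (m * n))


def sensitivity(preds: ScoredPredictions) -> float:
    """TP / (all positives) at the classification threshold."""
    m = int(preds.y_true.sum())
    if m == 0:
        raise UndefinedMetricError("sensitivity undefined with no positives")
    tp = int((preds.y_pred & preds.y_true).sum())
    return tp / m


def precision(preds: ScoredPredictions) -> float:
    """TP / (TP + FP); 0 by convention when nothing is predicted positive."""
    predicted = int(preds.y_pred.sum())
    if predicted == 0:
        return 0.0
    tp = int((preds.y_pred & preds.y_true).sum())
    return tp / predicted


def f1(preds: ScoredPredictions) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both vanish."""
    p = precision(preds)
    s = sensitivity(preds)
    if p + s == 0:
        return 0.0
    return 2 * p * s / (p + s)


def average_precision(preds: ScoredPredictions) -> float:
    """Step-summed area under the precision-recall curve."""
    preds._require_both_classes()
    order = np.argsort(-preds.scores, kind="stable")
    y = preds.y_true[order]
    scores = preds.scores[order]
    m = int(y.sum())
    tp = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    # evaluate only at the last index of each distinct score (threshold steps)
    last_of_score = np.r_[scores[1:] != scores[:-1], True]
    prec_k = tp[last_of_score] / ranks[last_of_score]
    rec_k = tp[last_of_score] / m
    return float(np.sum(np.diff(np.r_[0.0, rec_k]) * prec_k))


def compute_all(preds: ScoredPredictions) -> dict[str, float]:
    """All four validation metrics as a name -> value mapping."""
    return {
        "auc": auc(preds),
        "sensitivity": sensitivity(preds),
        "f1": f1(preds),
        "average_precision": average_precision(preds),
    }
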