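"""Gradient-boosted classifier backend.

The pipeline's default (and only required) backend is XGBoost with the
hyperparameters used throughout the evaluation protocol: 144 estimators,
maximum depth 8, minimum child weight 5.  Any binary classifier exposing
``fit`` / ``predict_proba`` and per-feature importances can be plugged in
through the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import xgboost as xgb

from .errors import ProtocolError

__all__ = ["ClassifierSpec", "fit_classifier", "feature_importances"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters for the gradient-boosted trees backend."""

    n_estimators: int = 144
    max_depth: int = 8
    min_child_weight: float = 5.0
    positive_class_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators <= 0 or self.max_depth <= 0 or self.min_child_weight <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.positive_class_weight < 0:
            raise ValueError("positive_class_weight must be >= 0")

    def with_weight(self, w: float) -> "ClassifierSpec":
        return replace(self, positive_class_weight=w)

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return replace(self, seed=seed)


def fit_classifier(X, y, spec: ClassifierSpec = ClassifierSpec()) -> xgb.XGBClassifier:
    """Train the boosted-tree model; deterministic given ``spec.seed``.

    Raises :class:`ProtocolError` when the training data contains a single
    class (naming the class counts).
    """
    y = np.asarray(y).astype(int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ProtocolError(
            f"training data single-class: {n_pos} positives, {n_neg} negatives"
        )
    model = xgb.XGBClassifier(
        n_estimators=spec.n_estimators,
        max_depth=spec.max_depth,
        min_child_weight=spec.min_child_weight,
        scale_pos_weight=spec.positive_class_weight,
        random_state=spec.seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    model.fit(np.asarray(X), y)
    return model


def feature_importances(model: xgb.XGBClassifier, n_features: int) -> np.ndarray:
    """Per-feature gain importances, zero for features never split on."""
    booster = model.get_booster()
    scores = booster.get_score(importance_type="gain")
    out = np.zeros(n_features)
    for key, value in scores.items():
        out[int(key.lstrip("f"))] = value
    return out
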