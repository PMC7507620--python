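"""Class-imbalance handling: random under/oversampling and cost weighting.

All resampling operates on sample *indices*, never on feature matrices, so a
single featurization serves every strategy, and it is applied to derivation
samples only — the validation set is always scored at its natural imbalance.

A ratio is the desired positives:negatives proportion, e.g. ``(1, 2)`` for
one positive per two negatives.  The derivation-set ratio sweep enumerates
10:1, 9:1, ..., 1:1, 1:2, ..., 1:10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ProtocolError

__all__ = [
    "ResampleSpec",
    "undersample",
    "oversample",
    "cost_weight",
    "resample_indices",
    "default_ratio_grid",
]


@dataclass(frozen=True)
class ResampleSpec:
    """How to rebalance the derivation set before training.

    ``ratio`` is (positives, negatives); it is ignored by ``cost_sensitive``
    and ``none``.
    """

    strategy: str = "undersample"  # undersample | oversample | cost_sensitive | none
    ratio: tuple[int, int] = (1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("undersample", "oversample", "cost_sensitive", "none"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if min(self.ratio) < 1:
            raise ValueError("ratio components must be >= 1")


def _split_classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y).astype(bool)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) == 0 or len(neg) == 0:
        raise ProtocolError(
            f"resampling requires both classes; got {len(pos)} positives and "
            f"{len(neg)} negatives"
        )
    return pos, neg


def undersample(y, spec: ResampleSpec) -> np.ndarray:
    """Indices after randomly dropping majority samples to reach the ratio.

    Every minority sample is kept.  If the ratio asks for more majority
    samples than exist, all are kept and a warning is issued.  Deterministic
    given ``spec.seed``.
    """
    pos, neg = _split_classes(y)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    r_min, r_maj = spec.ratio if minority is pos else spec.ratio[::-1]
    target = int(len(minority) * r_maj // r_min)
    rng = np.random.default_rng(spec.seed)
    if target >= len(majority):
        if target > len(majority):
            warnings.warn(
                f"undersampling ratio {spec.ratio} needs {target} majority "
                f"samples but only {len(majority)} exist; keeping all",
                stacklevel=2,
            )
        kept = majority
    else:
        kept = rng.choice(majority, size=target, replace=False)
    return np.sort(np.concatenate([minority, kept]))


def oversample(y, spec: ResampleSpec) -> np.ndarray:
    """Indices after duplicating minority samples (with replacement) to the
    ratio.  Nothing is ever dropped; an already-satisfied ratio is returned
    unchanged."""
    pos, neg = _split_classes(y)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    r_min, r_maj = spec.ratio if minority is pos else spec.ratio[::-1]
    target = int(len(majority) * r_min // r_maj)
    rng = np.random.default_rng(spec.seed)
    out = np.concatenate([pos, neg])
    if target > len(minority):
        extra = rng.choice(minority, size=target - len(minority), replace=True)
        out = np.concatenate([out, extra])
    return np.sort(out)


def cost_weight(y) -> float:
    """The positive-class weight for cost-sensitive boosting: n_neg / n_pos."""
    pos, neg = _split_classes(y)
    return len(neg) / len(pos)


def resample_indices(y, spec: ResampleSpec) -> tuple[np.ndarray, float]:
    """Apply a :class:`ResampleSpec`; returns (indices, positive-class weight)."""
    if spec.strategy == "undersample":
        return undersample(y, spec), 1.0
    if spec.strategy == "oversample":
        return oversample(y, spec), 1.0
    if spec.strategy == "cost_sensitive":
        return np.arange(len(np.asarray(y))), cost_weight(y)
    return np.arange(len(np.asarray(y))), 1.0


def default_ratio_grid() -> list[tuple[int, int]]:
    """The positives:negatives sweep 10:1, 9:1, ..., 1:1, 1:2, ..., 1:10."""
    return [(k, 1) for k in range(10, 0, -1)] + [(1, k) for k in range(2, 11)]
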