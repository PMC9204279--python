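"""Training loss and evaluation indices for binary segmentation.

The training objective is the soft Dice loss

    DL = 1 - (2 |X∩Y| + ε) / (|X| + |Y| + ε)

with the soft reading |X∩Y| = Σ p·t, |Y| = Σ p over predicted probabilities,
which handles the extreme foreground/background imbalance of a small gland on
a full CT slice.  Evaluation uses the hard-mask indices DSC, JSC, PPV, SE and
the exact (maximum, not 95th-percentile) symmetric Hausdorff distance.

Conventions for degenerate cases: when both masks are empty, DSC and JSC are
reported as 1.0 (perfect agreement on "nothing"); PPV is NaN when nothing is
predicted, SE is NaN when the target is empty (undefined ratios, excluded
from aggregation); the Hausdorff distance is +inf when exactly one mask is
empty and 0 when both are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .nn.autodiff import Tensor, soft_dice_loss

__all__ = [
    "ConfusionCounts",
    "MetricVector",
    "dice_loss",
    "confusion_counts",
    "overlap_metrics",
    "hausdorff_distance",
    "evaluate_pair",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricVector:
    dsc: float
    jsc: float
    ppv: float
    se: float
    hd: float


def dice_loss(pred, target, eps: float = 1.0):
    """Soft Dice loss (batch mean).

    Accepts a plain array (returns a float) or an autodiff ``Tensor`` (returns
    a scalar ``Tensor`` usable for backprop).  ``pred`` values must lie in
    [0, 1]; ``target`` must be binary and the same shape.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    t = np.asarray(target)
    if not np.isin(t, (0, 1)).all():
        raise ValueError("target mask must be binary {0,1}")
    if isinstance(pred, Tensor):
        return soft_dice_loss(pred, t, eps)
    p = np.asarray(pred, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.ndim <= 2:  # single sample
        p = p[None]
        t = t[None]
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    denom = t.sum(axis=axes) + p.sum(axis=axes) + eps
    return float((1.0 - (2.0 * inter + eps) / denom).mean())


def _check_binary(mask, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} must be binary {{0,1}}")
    return m.astype(bool)


def confusion_counts(pred, target) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN between two binary masks of identical shape."""
    p = _check_binary(pred, "pred")
    t = _check_binary(target, "target")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(DSC, JSC, PPV, SE) from confusion counts.

    DSC = 2TP/(2TP+FP+FN), JSC = TP/(TP+FP+FN), PPV = TP/(TP+FP),
    SE = TP/(TP+FN).  Empty denominators follow the module conventions
    (DSC/JSC -> 1.0 for two empty masks; PPV/SE -> NaN).
    """
    tp, fp, fn = c.tp, c.fp, c.fn
    dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    jsc = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    return dsc, jsc, ppv, se


def hausdorff_distance(pred, target, spacing=(1.0, 1.0)) -> float:
    """Exact symmetric Hausdorff distance between foreground point sets.

    H(X,Y) = max(h(X,Y), h(Y,X)) with h the directed max-min Euclidean
    distance; coordinates are scaled by per-axis ``spacing`` (mm per pixel)
    so the result is in mm when spacing is physical, else pixels.
    """
    p = _check_binary(pred, "pred")
    t = _check_binary(target, "target")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    sp = np.asarray(spacing, dtype=float)
    pp = np.argwhere(p) * sp
    tt = np.argwhere(t) * sp
    if len(pp) == 0 and len(tt) == 0:
        return 0.0
    if len(pp) == 0 or len(tt) == 0:
        return float("inf")
    return float(max(directed_hausdorff(pp, tt)[0], directed_hausdorff(tt, pp)[0]))


def evaluate_pair(pred, target, spacing=(1.0, 1.0)) -> MetricVector:
    """All five indices for one predicted/reference mask pair."""
    dsc, jsc, ppv, se = overlap_metrics(confusion_counts(pred, target))
    return MetricVector(dsc, jsc, ppv, se, hausdorff_distance(pred, target, spacing))
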