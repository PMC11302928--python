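"""Losses and evaluation metrics for multi-class tumor segmentation.

Hard metrics (accuracy, precision, sensitivity, specificity, Dice) are
computed from per-class confusion counts on argmax label masks — the
set-cardinality definitions ``sensitivity = |X1 ∩ G1| / |G1|`` and
``specificity = |X0 ∩ G0| / |G0|``. Losses are computed from soft
probabilities so they stay differentiable:

* **Tversky loss** ``1 - (TP + s) / (TP + α·FN + β·FP + s)`` with soft counts
  ``TP = Σ y_true·y_pred``, ``FP = Σ (1-y_true)·y_pred``,
  ``FN = Σ y_true·(1-y_pred)`` summed over all pixels and channels. With
  ``α = β = 0.5`` and vanishing smooth it reduces to one minus the soft Dice.
* **Boundary loss** ``boundary_weight · mean |Sobel(y_true) - Sobel(y_pred)|``
  where Sobel is the standard 3x3 gradient-magnitude operator applied per
  class channel with zero padding.

Composite BraTS regions: whole tumor WT = {1, 2, 3}, tumor core TC = {1, 3},
enhancing tumor ET = {3}, under the label convention 0 background,
1 necrotic/non-enhancing core, 2 edema, 3 enhancing.

Degenerate denominators follow the standard empty-slice convention: if the
relevant ground-truth set is empty, the metric is 1.0 when the prediction is
also empty and 0.0 otherwise; occurrences are logged at DEBUG level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .exceptions import ConfigurationError, DataError, ShapeError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "TverskyParams",
    "BoundaryParams",
    "MetricReport",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "precision_accuracy_dice",
    "dice_coefficient",
    "one_hot",
    "soft_counts",
    "tversky_loss",
    "sobel_edges",
    "boundary_loss",
    "brats_regions",
    "evaluate",
    "cross_entropy_graph",
    "tversky_loss_graph",
    "boundary_loss_graph",
    "DEFAULT_CLASS_NAMES",
]

DEFAULT_CLASS_NAMES = ("background", "necrosis", "edema", "enhancing")

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float32)
SOBEL_Y = SOBEL_X.T.copy()


# --------------------------------------------------------------------------
# confusion counts and hard metrics
# --------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN (integers for hard masks, reals for soft counts)."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(truth: np.ndarray, pred: np.ndarray, k: int) -> ConfusionCounts:
    """Confusion counts for class ``k`` between two label masks."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ShapeError(f"mask shapes differ: {truth.shape} vs {pred.shape}")
    t = truth == k
    p = pred == k
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = truth.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _empty_denominator(agrees_empty: bool, what: str) -> float:
    logger.debug("empty denominator for %s; returning %s sentinel",
                 what, 1.0 if agrees_empty else 0.0)
    return 1.0 if agrees_empty else 0.0


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP / (TP + FN)."""
    denom = c.tp + c.fn
    if denom == 0:
        return _empty_denominator(c.fp == 0, "sensitivity (empty truth)")
    return c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN / (TN + FP)."""
    denom = c.tn + c.fp
    if denom == 0:
        return _empty_denominator(c.fn == 0, "specificity (no negatives)")
    return c.tn / denom


def precision_accuracy_dice(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, accuracy, Dice) from one set of confusion counts."""
    if c.tp + c.fp == 0:
        precision = _empty_denominator(c.fn == 0, "precision (empty prediction)")
    else:
        precision = c.tp / (c.tp + c.fp)
    accuracy = (c.tp + c.tn) / c.total if c.total else 0.0
    if 2 * c.tp + c.fp + c.fn == 0:
        dice = _empty_denominator(True, "dice (both empty)")
    else:
        dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return precision, accuracy, dice


def dice_coefficient(truth: np.ndarray, pred: np.ndarray, k: int = 1) -> float:
    """Dice overlap of class ``k`` between two label masks."""
    _, _, dice = precision_accuracy_dice(confusion_counts(truth, pred, k))
    return dice


# --------------------------------------------------------------------------
# soft losses
# --------------------------------------------------------------------------

@dataclass
class TverskyParams:
    """Asymmetric overlap-loss weights: ``alpha`` penalizes FN, ``beta`` FP."""

    alpha: float = 0.7
    beta: float = 0.3
    smooth: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ConfigurationError("alpha and beta must be non-negative")
        if self.smooth <= 0:
            raise ConfigurationError("smooth must be positive")


@dataclass
class BoundaryParams:
    boundary_weight: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.boundary_weight) or self.boundary_weight < 0:
            raise ConfigurationError("boundary_weight must be finite and >= 0")


def one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """Label mask -> (H, W, K) one-hot tensor."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= n_classes:
        raise DataError(
            f"labels outside [0, {n_classes - 1}]: "
            f"{sorted(np.unique(mask[(mask < 0) | (mask >= n_classes)]).tolist())}")
    return np.eye(n_classes, dtype=np.float32)[mask]


def soft_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """Soft (TP, FP, FN) summed over all pixels and channels."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ShapeError(f"shapes differ: {y_true.shape} vs {y_pred.shape}")
    tp = float(np.sum(y_true * y_pred))
    fp = float(np.sum((1.0 - y_true) * y_pred))
    fn = float(np.sum(y_true * (1.0 - y_pred)))
    return tp, fp, fn


def tversky_loss(y_true: np.ndarray, y_pred: np.ndarray,
                 params: TverskyParams | None = None,
                 per_class: bool = False) -> float:
    """Soft Tversky loss over the flattened tensor (or averaged per class)."""
    params = params if params is not None else TverskyParams()
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ShapeError(f"shapes differ: {y_true.shape} vs {y_pred.shape}")
    if per_class:
        k = y_true.shape[-1]
        losses = [
            tversky_loss(y_true[..., c], y_pred[..., c], params)
            for c in range(k)
        ]
        return float(np.mean(losses))
    tp, fp, fn = soft_counts(y_true, y_pred)
    index = (tp + params.smooth) / (tp + params.alpha * fn
                                    + params.beta * fp + params.smooth)
    return float(1.0 - index)


def sobel_edges(img: np.ndarray) -> np.ndarray:
    """Gradient magnitude via the standard 3x3 Sobel kernels.

    Borders are handled by edge replication, so constant images produce a
    strictly zero edge map and the response is invariant to constant offsets.
    """
    img = np.asarray(img, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == 1:
        img = img[..., 0]
    if img.ndim != 2:
        raise ShapeError(
            f"sobel_edges expects a single-channel image, got shape {img.shape}")
    gx = ndimage.correlate(img, SOBEL_X, mode="nearest")
    gy = ndimage.correlate(img, SOBEL_Y, mode="nearest")
    return np.sqrt(gx * gx + gy * gy)


def boundary_loss(y_true: np.ndarray, y_pred: np.ndarray,
                  params: BoundaryParams | None = None) -> float:
    """Mean absolute Sobel-edge difference, scaled by ``boundary_weight``."""
    params = params if params is not None else BoundaryParams()
    y_true = np.asarray(y_true, dtype=np.float32)
    y_pred = np.asarray(y_pred, dtype=np.float32)
    if y_true.shape != y_pred.shape:
        raise ShapeError(f"shapes differ: {y_true.shape} vs {y_pred.shape}")
    if y_true.ndim == 2:
        y_true = y_true[..., None]
        y_pred = y_pred[..., None]
    diffs = [
        np.abs(sobel_edges(y_true[..., k]) - sobel_edges(y_pred[..., k]))
        for k in range(y_true.shape[-1])
    ]
    return float(params.boundary_weight * np.mean(diffs))


# --------------------------------------------------------------------------
# composite regions and the full report
# --------------------------------------------------------------------------

def brats_regions(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(whole tumor, tumor core, enhancing tumor) binary masks."""
    mask = np.asarray(mask)
    bad = np.unique(mask[(mask < 0) | (mask > 3)])
    if bad.size:
        raise DataError(f"labels must be in 0..3, found {bad.tolist()}")
    wt = np.isin(mask, (1, 2, 3))
    tc = np.isin(mask, (1, 3))
    et = mask == 3
    return wt, tc, et


@dataclass
class MetricReport:
    """Per-class, macro-averaged, and composite-region evaluation metrics."""

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    composite_dice: dict[str, float]
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps({
            "per_class": self.per_class,
            "macro": self.macro,
            "composite_dice": self.composite_dice,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    def to_csv_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for cls, metrics in self.per_class.items():
            for name, value in metrics.items():
                row[f"{cls}_{name}"] = value
        for name, value in self.macro.items():
            row[f"macro_{name}"] = value
        for region, value in self.composite_dice.items():
            row[f"dice_{region}"] = value
        return row


def evaluate(truth: np.ndarray, prob: np.ndarray,
             class_names: tuple[str, ...] | None = None) -> MetricReport:
    """Full metric report for one ground-truth mask vs a probability map.

    ``prob`` may also be a hard label mask of the same shape as ``truth``.
    Argmax ties resolve to the lowest class index.
    """
    truth = np.asarray(truth)
    prob = np.asarray(prob)
    if prob.ndim == truth.ndim + 1:
        if prob.shape[:-1] != truth.shape:
            raise ShapeError(
                f"probability map {prob.shape} incompatible with truth {truth.shape}")
        n_classes = prob.shape[-1]
        pred = np.argmax(prob, axis=-1)
    elif prob.shape == truth.shape:
        pred = prob.astype(int)
        n_classes = int(max(truth.max(), pred.max())) + 1
    else:
        raise ShapeError(
            f"prediction {prob.shape} incompatible with truth {truth.shape}")
    names = class_names or tuple(
        DEFAULT_CLASS_NAMES[k] if k < len(DEFAULT_CLASS_NAMES) else f"class{k}"
        for k in range(n_classes))
    if len(names) != n_classes:
        raise ConfigurationError(
            f"{len(names)} class names given for {n_classes} classes")

    per_class: dict[str, dict[str, float]] = {}
    for k, name in enumerate(names):
        c = confusion_counts(truth, pred, k)
        prec, acc, dice = precision_accuracy_dice(c)
        per_class[name] = {
            "accuracy": acc,
            "precision": prec,
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "dice": dice,
        }
    macro = {
        metric: float(np.mean([per_class[n][metric] for n in names]))
        for metric in ("accuracy", "precision", "sensitivity", "specificity", "dice")
    }
    composite: dict[str, float] = {}
    if n_classes == 4:
        t_regions = brats_regions(truth)
        p_regions = brats_regions(pred)
        for region, t_bin, p_bin in zip(("wt", "tc", "et"), t_regions, p_regions):
            composite[region] = dice_coefficient(
                t_bin.astype(int), p_bin.astype(int), k=1)
    return MetricReport(per_class=per_class, macro=macro,
                        composite_dice=composite, class_names=tuple(names))


# --------------------------------------------------------------------------
# differentiable (graph) versions used by the training loop
# --------------------------------------------------------------------------

def cross_entropy_graph(logits: nn.Tensor, y_true: np.ndarray) -> nn.Tensor:
    """Categorical cross-entropy, mean over pixels; ``y_true`` one-hot NHWK."""
    logp = nn.log_softmax(logits, axis=-1)
    picked = (logp * nn.Tensor(y_true)).sum(axis=-1)
    return -picked.mean()


def tversky_loss_graph(probs: nn.Tensor, y_true: np.ndarray,
                       params: TverskyParams | None = None) -> nn.Tensor:
    params = params if params is not None else TverskyParams()
    t = nn.Tensor(np.asarray(y_true, dtype=np.float32))
    tp = (t * probs).sum()
    fp = ((1.0 - t) * probs).sum()
    fn = (t * (1.0 - probs)).sum()
    index = (tp + params.smooth) / (tp + params.alpha * fn
                                    + params.beta * fp + params.smooth)
    return 1.0 - index


def boundary_loss_graph(probs: nn.Tensor, y_true: np.ndarray,
                        params: BoundaryParams | None = None) -> nn.Tensor:
    """Differentiable boundary loss on an NHWK probability tensor."""
    params = params if params is not None else BoundaryParams()
    n, h, w, k = probs.shape
    # fold classes into the batch so one fixed-kernel conv does every channel;
    # replicate-pad + crop reproduces sobel_edges' edge handling
    flat = probs.transpose((0, 3, 1, 2)).reshape(n * k, h, w, 1)
    padded = nn.pad_replicate(flat, 1)
    kx = nn.Tensor(SOBEL_X[:, :, None, None])
    ky = nn.Tensor(SOBEL_Y[:, :, None, None])
    eps = 1e-8  # keeps sqrt differentiable at flat regions
    gx = nn.crop_center(nn.conv2d(padded, kx), 1)
    gy = nn.crop_center(nn.conv2d(padded, ky), 1)
    mag_pred = (gx * gx + gy * gy + eps).sqrt()
    true = np.asarray(y_true, dtype=np.float32)
    mag_true = np.stack([
        sobel_edges(true[i, :, :, c]) for i in range(n) for c in range(k)
    ])[..., None]
    return (mag_pred - nn.Tensor(mag_true)).abs().mean() * params.boundary_weight
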