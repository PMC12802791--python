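"""Per-image segmentation metrics: 2-class mean IOU, pixel AUROC, accuracy.

The clot occupies a small fraction of the frame, so plain accuracy is
dominated by background and the averaged per-class IOU (background and clot)
is the headline metric.  AUROC is computed on the pre-binarization
probability map — a binary predictor would collapse the ROC curve to a single
point — using the rank (Mann-Whitney) formulation with midrank tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .model import NetworkParameters, predict
from .preprocess import MaskPair

__all__ = [
    "PerImageMetrics",
    "binarize",
    "class_iou",
    "mean_iou_2class",
    "pixel_auroc",
    "pixel_accuracy",
    "evaluate_predictions",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class PerImageMetrics:
    """Metrics for one test image; every value lies in [0, 1]."""

    id: str
    mean_iou_2class: float
    clot_iou: float
    auroc: float
    accuracy: float


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (p == threshold) go to foreground."""
    pred = np.asarray(pred)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if pred.size and (pred.min() < 0.0 or pred.max() > 1.0):
        raise ValueError("probability map values must lie in [0, 1]")
    return (pred >= threshold).astype(np.uint8)


def class_iou(pred: np.ndarray, target: np.ndarray, cls: int) -> float:
    """Intersection over union of one class; empty union counts as 1.0."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    _check_shapes(pred, target)
    p = pred == cls
    t = target == cls
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def mean_iou_2class(pred: np.ndarray, target: np.ndarray) -> float:
    """Unweighted mean of background and foreground IOU."""
    return 0.5 * (class_iou(pred, target, 0) + class_iou(pred, target, 1))


def pixel_auroc(scores: np.ndarray, target: np.ndarray) -> float:
    """Pixel-level area under the ROC curve of ``scores`` against ``target``.

    Raises ``ValueError`` when the target contains a single class — the ROC
    curve, and hence the AUROC, is undefined there.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    target = np.asarray(target).ravel()
    classes = np.unique(target)
    if classes.size < 2:
        raise ValueError("AUROC undefined: target contains a single class")
    return float(roc_auc_score(target, scores))


def pixel_accuracy(pred: np.ndarray, target: np.ndarray) -> float:
    """Fraction of pixels predicted correctly."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    _check_shapes(pred, target)
    return float((pred == target).mean())


def evaluate_predictions(
    probs: np.ndarray,
    pairs: list[MaskPair],
    threshold: float = 0.5,
) -> list[PerImageMetrics]:
    """Score probability maps (one per pair) against the pairs' clot masks."""
    if len(probs) != len(pairs):
        raise ValueError("need one probability map per mask pair")
    out = []
    for prob, pair in zip(probs, pairs):
        image_id = pair.source_id or f"image_{len(out):04d}"
        try:
            target = pair.clot_mask
            pred = binarize(prob, threshold)
            out.append(
                PerImageMetrics(
                    id=image_id,
                    mean_iou_2class=mean_iou_2class(pred, target),
                    clot_iou=class_iou(pred, target, 1),
                    auroc=pixel_auroc(prob, target),
                    accuracy=pixel_accuracy(pred, target),
                )
            )
        except ValueError as exc:
            raise ValueError(f"image {image_id}: {exc}") from exc
    return out


def evaluate_dataset(
    params: NetworkParameters,
    pairs: list[MaskPair],
    threshold: float = 0.5,
    batch_size: int = 32,
) -> list[PerImageMetrics]:
    """Predict every pair's dot mask and score against its clot mask.

    AUROC uses the raw probability map; IOU and accuracy use the map
    binarized at ``threshold``.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one mask pair")
    probs = []
    for s in range(0, len(pairs), batch_size):
        chunk = pairs[s:s + batch_size]
        x = np.stack([p.dot_mask for p in chunk]).astype(np.float32)
        probs.extend(predict(params, x))
    return evaluate_predictions(np.asarray(probs), pairs, threshold)
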