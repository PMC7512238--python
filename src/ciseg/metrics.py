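"""Segmentation evaluation: binarization, Jaccard/Dice, label accuracy.

The Jaccard (Tanimoto) coefficient between two binary masks is
``|A & B| / |A | B|``; zero means disjoint foregrounds, one means perfect
agreement.  Dice is tied to it by ``D = 2 J / (1 + J)``.  The evaluation
protocol binarizes grayscale images at a fixed level (0.5 by default)
with a strict "greater than" rule, and compares label maps by per-pixel
accuracy after establishing the class correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ci_filter import as_gray_image

__all__ = [
    "SegScore",
    "binarize",
    "jaccard",
    "label_accuracy",
    "render_labels",
]


@dataclass(frozen=True)
class SegScore:
    jaccard: float
    dice: float


def binarize(image: np.ndarray, level: float = 0.5) -> np.ndarray:
    """Binary mask: pixel is foreground iff intensity is strictly > level."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    return (as_gray_image(image) > level).astype(np.uint8)


def jaccard(a: np.ndarray, b: np.ndarray) -> SegScore:
    """Jaccard and Dice overlap of two equal-shape binary masks.

    Two empty masks agree perfectly by convention (J = D = 1).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return SegScore(jaccard=1.0, dice=1.0)
    j = inter / union
    return SegScore(jaccard=j, dice=2.0 * j / (1.0 + j))


def _relabel_by_intensity(labels: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Renumber classes in ascending order of their mean source intensity."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    means = [float(image[labels == k].mean()) for k in present]
    order = present[np.argsort(means, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order)}
    out = np.empty_like(labels)
    for old, new in remap.items():
        out[labels == old] = new
    return out


def label_accuracy(
    pred: np.ndarray,
    truth: np.ndarray,
    pred_image: np.ndarray | None = None,
    truth_image: np.ndarray | None = None,
) -> float:
    """Fraction of pixels assigned the matching class.

    Class numbering of the two maps need not agree.  If source images are
    provided, classes on each side are first renumbered by ascending class
    mean intensity (the natural ordering for threshold-based labels).
    Otherwise the correspondence maximizing pixel agreement is found by
    optimal one-to-one assignment on the confusion matrix.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred_image is not None:
        pred = _relabel_by_intensity(pred, as_gray_image(pred_image))
    if truth_image is not None:
        truth = _relabel_by_intensity(truth, as_gray_image(truth_image))
    if pred_image is not None and truth_image is not None:
        return float(np.mean(pred == truth))
    k = int(max(pred.max(), truth.max())) + 1
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (pred.ravel().astype(np.int64),
                     truth.ravel().astype(np.int64)), 1)
    rows, cols = linear_sum_assignment(conf, maximize=True)
    return float(conf[rows, cols].sum() / pred.size)


def render_labels(labels: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Grayscale rendering of a label map: class k -> its class mean intensity.

    Mimics the colored-segmentation-to-grayscale step of the evaluation
    chain without committing to a palette; the result can be binarized and
    scored with :func:`jaccard`.
    """
    arr = as_gray_image(image)
    labels = np.asarray(labels)
    if labels.shape != arr.shape:
        raise ValueError("labels and image must share a shape")
    out = np.zeros_like(arr)
    for k in np.unique(labels):
        sel = labels == k
        out[sel] = arr[sel].mean()
    return out
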