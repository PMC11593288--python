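"""Segmentation overlap metrics and a classical baseline segmenter.

Metrics follow the raw pixel-count definitions

    IoU      = TP / (TP + FP + FN)
    F        = TP / (TP + (FP + FN) / 2)      (the Dice / F-score)
    DiceLoss = 1 - F

which are linked by the identity F = 2·IoU / (1 + IoU).

The baseline segmenter (Otsu threshold + morphological cleanup + largest
particle) is a deterministic classical stand-in so the full pipeline runs
end-to-end on synthetic pseudo-B-mode images; predicted masks from any
external segmentation model can be evaluated with the same metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from . import maskops

__all__ = ["SegMetrics", "seg_metrics", "baseline_segmenter"]


@dataclass(frozen=True)
class SegMetrics:
    TP: int
    FP: int
    FN: int
    IoU: float
    F: float
    DiceLoss: float


def seg_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Pixelwise overlap metrics between a predicted and a reference mask.

    Raises
    ------
    ValueError
        On dimension mismatch or an empty reference mask.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not truth.any():
        raise ValueError("reference mask is empty")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    denom_iou = tp + fp + fn
    iou = tp / denom_iou if denom_iou else 1.0
    f = tp / (tp + 0.5 * (fp + fn)) if (tp + fp + fn) else 1.0
    return SegMetrics(TP=tp, FP=fp, FN=fn, IoU=iou, F=f, DiceLoss=1.0 - f)


def baseline_segmenter(
    image: np.ndarray, min_size: int = maskops.DEFAULT_MIN_SIZE
) -> np.ndarray:
    """Segment the liver region from a grayscale image, classically.

    Global Otsu threshold, morphological closing then opening to heal
    speckle, and reduction to the largest filled particle.  Deterministic.

    Raises
    ------
    ValueError
        If the image is uniform (no threshold exists) or no particle of at
        least ``min_size`` px is found.
    """
    image = np.asarray(image)
    if image.min() == image.max():
        raise ValueError("uniform image: no foreground found")
    t = threshold_otsu(image)
    mask = image > t  # Otsu's value is the top of the background class
    mask = ndi.binary_closing(mask, structure=disk(3))
    mask = ndi.binary_opening(mask, structure=disk(2))
    if not mask.any():
        raise ValueError("no foreground found after thresholding")
    return maskops.largest_particle(mask, min_size=min_size)
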