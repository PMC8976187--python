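"""Segmentation and classification metrics.

Segmentation quality between a predicted and a ground-truth WBC mask is
summarized by pixel accuracy, the structural similarity index (SSIM) and the
Dice similarity coefficient; classification quality by accuracy, precision
and recall derived from TP/TN/FP/FN confusion counts.

Definitions (counts at pixel or image level):

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    dice      = 2 TP / (2 TP + FP + FN) = 2|A & B| / (|A| + |B|)

SSIM uses a 7x7 uniform sliding window with the standard constants
C1 = (0.01 L)^2, C2 = (0.03 L)^2 for dynamic range L, mean-aggregated over
windows.  Rates with zero denominator are reported as NaN (flagged
undefined), never silently zero; the Dice of two empty masks is defined as
1.0 with a warning (perfect agreement on "nothing to segment").

Printed-table comparisons round half away from zero to 4 decimals
(:func:`round_half_away`), matching how the reference tables print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity as _sk_ssim

from .errors import ParameterError, SemanticError
from .io_color import BinaryMask, ChannelImage

__all__ = [
    "ConfusionCounts",
    "SegmentationScore",
    "BatchScores",
    "confusion_counts",
    "classification_metrics",
    "dice_coefficient",
    "pixel_accuracy",
    "ssim",
    "evaluate_batch",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 4) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN tallies.

    Counts are reals: pixel-level tallies are integers, but run-averaged
    image-level tallies may be fractional.
    """

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SegmentationScore:
    """Per-pair segmentation quality triple."""

    pixel_accuracy: float
    ssim: float
    dice: float


def _mask_pair(pred: BinaryMask, truth: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    if pred.shape != truth.shape:
        raise SemanticError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return pred.bool, truth.bool


def confusion_counts(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Pixel-level confusion tallies between predicted and true masks."""
    p, t = _mask_pair(pred, truth)
    return ConfusionCounts(
        tp=float(np.sum(p & t)),
        tn=float(np.sum(~p & ~t)),
        fp=float(np.sum(p & ~t)),
        fn=float(np.sum(~p & t)),
    )


def _rate(num: float, den: float) -> float:
    if den <= 0:
        warnings.warn("zero denominator: rate reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision and recall from confusion counts (unrounded)."""
    return {
        "accuracy": _rate(c.tp + c.tn, c.total),
        "precision": _rate(c.tp, c.tp + c.fp),
        "recall": _rate(c.tp, c.tp + c.fn),
    }


def dice_coefficient(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); two empty masks score 1.0 (warned)."""
    p, t = _mask_pair(pred, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * float(np.sum(p & t)) / denom


def pixel_accuracy(pred: BinaryMask, truth: BinaryMask) -> float:
    """Fraction of pixels on which the two masks agree."""
    p, t = _mask_pair(pred, truth)
    return float(np.mean(p == t))


def _as_plane(x: ChannelImage | BinaryMask | np.ndarray) -> tuple[np.ndarray, float]:
    """Coerce to a float plane plus its natural dynamic range."""
    if isinstance(x, BinaryMask):
        return x.pixels.astype(np.float64), 1.0
    if isinstance(x, ChannelImage):
        return x.pixels.astype(np.float64), 255.0
    arr = np.asarray(x)
    if arr.dtype == bool:
        return arr.astype(np.float64), 1.0
    return arr.astype(np.float64), 255.0


def ssim(
    a: ChannelImage | BinaryMask | np.ndarray,
    b: ChannelImage | BinaryMask | np.ndarray,
    data_range: float | None = None,
    win_size: int = 7,
) -> float:
    """Mean structural similarity over a uniform sliding window.

    The dynamic range defaults to 1 for masks and 255 for channels; pass
    ``data_range`` to override.  Symmetric in its arguments.
    """
    pa, la = _as_plane(a)
    pb, lb = _as_plane(b)
    if pa.shape != pb.shape:
        raise SemanticError(f"ssim inputs differ in shape: {pa.shape} vs {pb.shape}")
    L = float(data_range) if data_range is not None else max(la, lb)
    if min(pa.shape) < win_size:
        raise ParameterError(
            f"image {pa.shape} smaller than the {win_size}x{win_size} SSIM window"
        )
    return float(
        _sk_ssim(pa, pb, win_size=win_size, data_range=L, gaussian_weights=False)
    )


@dataclass
class BatchScores:
    """Per-pair scores plus unweighted means for a batch of mask pairs."""

    scores: pd.DataFrame  # columns: pixel_accuracy, ssim, dice

    @property
    def means(self) -> pd.Series:
        return self.scores.mean()

    def table(self) -> pd.DataFrame:
        """Mean scores laid out like the published segmentation summary table."""
        m = self.means
        return pd.DataFrame(
            {
                "Triple thresholding": [
                    round_half_away(m["pixel_accuracy"]),
                    round_half_away(m["ssim"]),
                    round_half_away(m["dice"]),
                ]
            },
            index=["Accuracy", "Structural similarity", "Dice similarity coefficient"],
        )


def evaluate_batch(pairs: list[tuple[BinaryMask, BinaryMask]]) -> BatchScores:
    """Score a list of (predicted, truth) mask pairs."""
    if not pairs:
        raise ParameterError("evaluate_batch needs at least one (pred, truth) pair")
    rows = []
    for pred, truth in pairs:
        rows.append(
            {
                "pixel_accuracy": pixel_accuracy(pred, truth),
                "ssim": ssim(pred, truth),
                "dice": dice_coefficient(pred, truth),
            }
        )
    return BatchScores(pd.DataFrame(rows))
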