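"""Per-case geometric metrics: craniocaudal length, Dice overlap, outliers.

Length is the contiguous craniocaudal extent of the segmentation (number
of axial slices between the lowest and highest occupied slice, inclusive,
times slice thickness); contours spanning at least 18 cm are classified
full-length, shorter ones partial — the split between whole-organ contours
drawn for conventionally fractionated radiotherapy and tumour-level
partial contours drawn for SBRT.

Dice is the standard volumetric overlap 2|A∩B| / (|A|+|B|) over voxel
counts.  When the reference is a partial contour, ``partial_dice``
restricts the comparison to the axial slices where the reference has
foreground, so a full-length prediction is not penalized for correctly
segmenting beyond a truncated ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mask_io import LabelMask

__all__ = [
    "DicePair",
    "LengthResult",
    "segmentation_length",
    "volumetric_dice",
    "partial_dice",
    "outlier_counts",
    "DEFAULT_LENGTH_THRESHOLD_CM",
    "DEFAULT_OUTLIER_THRESHOLDS",
]

DEFAULT_LENGTH_THRESHOLD_CM = 18.0
DEFAULT_OUTLIER_THRESHOLDS = (0.20, 0.40, 0.50, 0.70)


@dataclass
class DicePair:
    """A predicted and a reference mask on the same grid."""

    predicted: LabelMask
    reference: LabelMask

    def __post_init__(self) -> None:
        if self.predicted.shape != self.reference.shape:
            raise ValueError(
                f"grid shapes differ: {self.predicted.shape} vs {self.reference.shape}"
            )
        if self.predicted.spacing != self.reference.spacing:
            raise ValueError(
                f"grid spacings differ: {self.predicted.spacing} vs {self.reference.spacing}"
            )


@dataclass
class LengthResult:
    """Craniocaudal extent and the full/partial classification."""

    length_cm: float
    n_slices: int
    threshold_cm: float = DEFAULT_LENGTH_THRESHOLD_CM

    @property
    def classification(self) -> str:
        return "full" if self.length_cm >= self.threshold_cm else "partial"


def segmentation_length(
    mask: LabelMask, threshold_cm: float = DEFAULT_LENGTH_THRESHOLD_CM
) -> LengthResult:
    """Craniocaudal segmentation length and full/partial classification.

    length_cm = (z_max - z_min + 1) * sz / 10 over occupied axial slices;
    ``n_slices`` counts occupied slices only, so it is smaller than the
    extent when gaps exist (a flag for pathological inputs).
    """
    if mask.is_empty:
        raise ValueError("length is undefined for an empty mask")
    occupied = np.flatnonzero(mask.voxels.any(axis=(0, 1)))
    extent = int(occupied[-1] - occupied[0] + 1)
    length_cm = extent * mask.spacing[2] / 10.0
    return LengthResult(length_cm=length_cm, n_slices=len(occupied), threshold_cm=threshold_cm)


def volumetric_dice(pair: DicePair) -> float:
    """Volumetric Dice coefficient 2|Vp ∩ Vgt| / (|Vp| + |Vgt|) in [0, 1].

    Two empty masks are an error (a data problem, not a perfect score).
    """
    p = pair.predicted.voxels.astype(bool)
    r = pair.reference.voxels.astype(bool)
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        raise ValueError("Dice is undefined when both masks are empty")
    return 2.0 * int((p & r).sum()) / denom


def partial_dice(pair: DicePair) -> float:
    """Dice restricted to the axial slices where the reference has foreground."""
    r = pair.reference.voxels
    if not r.any():
        raise ValueError("partial Dice requires a non-empty reference")
    keep = r.any(axis=(0, 1))
    pred = np.where(keep[None, None, :], pair.predicted.voxels, 0)
    restricted = DicePair(
        LabelMask(pred, pair.predicted.spacing, pair.predicted.origin),
        pair.reference,
    )
    return volumetric_dice(restricted)


def outlier_counts(
    dice_values: list[float] | np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_OUTLIER_THRESHOLDS,
) -> pd.DataFrame:
    """Count Dice outliers at each threshold (inclusive: Dice <= threshold).

    Returns a DataFrame with columns threshold, count, proportion.
    """
    values = np.asarray(dice_values, dtype=float)
    if values.size == 0:
        raise ValueError("dice_values must be non-empty")
    if ((values < 0) | (values > 1)).any():
        raise ValueError("Dice values must lie in [0, 1]")
    rows = [
        {"threshold": t, "count": int((values <= t).sum()), "proportion": float((values <= t).mean())}
        for t in thresholds
    ]
    return pd.DataFrame(rows)
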