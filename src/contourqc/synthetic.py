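"""Synthetic esophagus-like tubular phantoms with controllable jitter.

Clinical contour data is private, so the validation substrate is a
generator of tubular 3D binary masks that emulate the geometry a clinician
produces when contouring a roughly cylindrical organ slice by slice:

* a smooth low-frequency sinusoidal centerline drift (anatomical curvature),
* mild per-slice radius variation,
* **per-slice lateral jitter** — independent uniform integer shifts of the
  disk center on each axial slice, the knob that models slice-to-slice
  contouring inconsistency,
* an optional 3-slice moving average of the centers, emulating the
  interpolation/smoothing tools some annotators use,
* an optional contiguous crop, emulating partial (tumour-level) contours.

Defaults describe a realistic full-length esophagus on a 1 mm grid:
20 cm long (200 slices), radius 8 mm with 0.5 mm per-slice variation, and
a 4 mm centerline drift.  All randomness is driven by a single integer
seed with integer-only jitter draws, so masks are bit-reproducible.

``generate_cohort`` builds multi-annotator cohorts from
:class:`AnnotatorStyle` descriptions (per-style jitter, length
distribution, partial-contour probability), measuring length and edge
roughness on each generated mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_stats import CohortRecord
from .mask_io import LabelMask
from .roughness import edge_roughness
from .seg_metrics import segmentation_length

__all__ = ["TubeConfig", "AnnotatorStyle", "generate_tube", "generate_cohort"]


@dataclass
class TubeConfig:
    """Parameters of one synthetic tubular mask (lengths in slices/pixels)."""

    n_slices: int = 200
    slice_spacing_mm: float = 1.0
    radius_px: float = 8.0
    radius_sd: float = 0.5
    centerline_amplitude_px: float = 4.0
    jitter_px: float = 0.0
    partial_fraction: float = 1.0
    smoothing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise ValueError(f"n_slices must be >= 3, got {self.n_slices}")
        if self.radius_px <= 0:
            raise ValueError(f"radius_px must be > 0, got {self.radius_px}")
        if self.jitter_px < 0:
            raise ValueError(f"jitter_px must be >= 0, got {self.jitter_px}")
        if not (0.0 < self.partial_fraction <= 1.0):
            raise ValueError(f"partial_fraction must be in (0, 1], got {self.partial_fraction}")
        if self.slice_spacing_mm <= 0:
            raise ValueError(f"slice_spacing_mm must be > 0, got {self.slice_spacing_mm}")


@dataclass
class AnnotatorStyle:
    """A contouring style: jitter level, length habits, partial tendency."""

    label: str
    jitter_px: float = 0.0
    length_distribution: tuple[float, float] = (20.0, 1.5)  # (mean_cm, sd_cm)
    partial_probability: float = 0.0
    smoothing: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.partial_probability <= 1.0):
            raise ValueError("partial_probability must be in [0, 1]")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if self.length_distribution[0] <= 0 or self.length_distribution[1] < 0:
            raise ValueError("length_distribution must be (mean_cm > 0, sd_cm >= 0)")


def generate_tube(config: TubeConfig) -> LabelMask:
    """Generate a tubular binary mask per the config; deterministic in seed.

    Each axial slice carries a filled disk whose center follows a smooth
    sinusoidal centerline plus an independent uniform integer jitter in
    [-jitter_px, +jitter_px] per in-plane axis.  With ``smoothing`` the
    centers are passed through a 3-slice moving average before drawing.
    With ``partial_fraction`` < 1 only a contiguous block of slices
    (random start) keeps its foreground.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_slices
    amp = config.centerline_amplitude_px
    jit = int(round(config.jitter_px))

    half = int(np.ceil(config.radius_px + 4 * config.radius_sd + amp + jit)) + 2
    size = 2 * half + 1
    c0 = float(half)

    z = np.arange(n)
    # one gentle period along the tube, different phases per axis
    cx = c0 + amp * np.sin(2 * np.pi * z / max(n, 2))
    cy = c0 + amp * np.sin(2 * np.pi * z / max(n, 2) + np.pi / 2)
    if jit > 0:
        cx = cx + rng.integers(-jit, jit + 1, size=n)
        cy = cy + rng.integers(-jit, jit + 1, size=n)
    radii = np.maximum(1.0, config.radius_px + config.radius_sd * rng.standard_normal(n))
    if config.smoothing:
        kernel = np.ones(3) / 3.0
        pad = lambda a: np.concatenate([a[:1], a, a[-1:]])  # noqa: E731
        cx = np.convolve(pad(cx), kernel, mode="valid")
        cy = np.convolve(pad(cy), kernel, mode="valid")

    X, Y = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    voxels = np.zeros((size, size, n), dtype=np.uint8)
    for k in range(n):
        voxels[:, :, k] = (X - cx[k]) ** 2 + (Y - cy[k]) ** 2 <= radii[k] ** 2

    if config.partial_fraction < 1.0:
        keep = max(1, int(round(config.partial_fraction * n)))
        start = int(rng.integers(0, n - keep + 1))
        voxels[:, :, :start] = 0
        voxels[:, :, start + keep:] = 0

    return LabelMask(voxels, spacing=(1.0, 1.0, config.slice_spacing_mm))


def generate_cohort(
    styles: list[AnnotatorStyle], cases_per_style: int, seed: int = 0
) -> tuple[list[LabelMask], list[CohortRecord]]:
    """Generate a multi-annotator cohort of tubes with measured metrics.

    For each style, segmented lengths are drawn from its normal length
    distribution (floored at 4 cm); cases flagged partial (with the
    style's probability) realize that length as a contiguous random-start
    crop of a nominally full-length tube.  Each record carries the length
    and edge roughness measured on the generated mask.
    """
    if not styles:
        raise ValueError("at least one style is required")
    if cases_per_style < 1:
        raise ValueError("cases_per_style must be >= 1")
    rng = np.random.default_rng(seed)
    masks: list[LabelMask] = []
    records: list[CohortRecord] = []
    for style in styles:
        mean_cm, sd_cm = style.length_distribution
        for i in range(cases_per_style):
            case_seed = int(rng.integers(0, 2**31 - 1))
            length_cm = max(4.0, float(rng.normal(mean_cm, sd_cm)))
            n_slices = max(3, int(round(length_cm * 10.0)))
            partial = bool(rng.random() < style.partial_probability)
            if partial:
                n_full = max(n_slices, 200)
                config = TubeConfig(
                    n_slices=n_full,
                    jitter_px=style.jitter_px,
                    smoothing=style.smoothing,
                    partial_fraction=n_slices / n_full,
                    seed=case_seed,
                )
            else:
                config = TubeConfig(
                    n_slices=n_slices,
                    jitter_px=style.jitter_px,
                    smoothing=style.smoothing,
                    seed=case_seed,
                )
            mask = generate_tube(config)
            length = segmentation_length(mask)
            rough = edge_roughness(mask, resample_to=None)
            masks.append(mask)
            records.append(
                CohortRecord(
                    case_id=f"{style.label}-{i:03d}",
                    annotator=style.label,
                    length_cm=length.length_cm,
                    roughness=rough.edge_roughness,
                )
            )
    return masks, records
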