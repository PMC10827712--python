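"""Binarized 2D coronal and sagittal projections of a 3D mask.

A projection collapses the mask along one in-plane axis: the coronal view
sums over the anterior–posterior (y) axis and retains (x, z); the sagittal
view sums over the left–right (x) axis and retains (y, z).  Sums are then
binarized — a pixel is foreground iff any voxel along the collapsed axis is
foreground — because only the support (the jagged silhouette produced by
slice-to-slice contour shifts) carries the roughness signal.

Array convention: ``pixels[u, z]`` with the retained in-plane axis first
and the axial slice axis second.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mask_io import LabelMask

__all__ = ["ProjectionImage", "project", "projection_area", "save_projection"]

_PLANES = {"coronal": 1, "sagittal": 0}  # axis of LabelMask summed out


@dataclass
class ProjectionImage:
    """Binary 2D projection ``pixels[u, z]`` of a segmentation.

    ``plane`` is ``"coronal"`` (collapsed over y, u = x) or ``"sagittal"``
    (collapsed over x, u = y); ``pixel_spacing`` is (mm per u-pixel,
    mm per z-pixel) inherited from the source mask.
    """

    pixels: np.ndarray
    plane: str
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.plane not in _PLANES:
            raise ValueError(f"plane must be one of {sorted(_PLANES)}, got {self.plane!r}")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got {self.pixels.ndim}D")
        if not np.isin(np.unique(self.pixels), (0, 1)).all():
            raise ValueError("pixels must contain only {0, 1}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def project(mask: LabelMask, plane: str) -> ProjectionImage:
    """Collapse ``mask`` into a binarized projection on the given plane.

    Pixel (u, z) is 1 iff any foreground voxel exists along the collapsed
    axis at that position.  Raises ``ValueError`` for an empty mask or an
    unknown plane.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}, got {plane!r}")
    if mask.is_empty:
        raise ValueError("cannot project an empty mask")
    axis = _PLANES[plane]
    pixels = (mask.voxels.sum(axis=axis) > 0).astype(np.uint8)
    kept = [i for i in range(3) if i != axis]
    spacing = (mask.spacing[kept[0]], mask.spacing[kept[1]])
    return ProjectionImage(pixels, plane=plane, pixel_spacing=spacing)


def projection_area(proj: ProjectionImage) -> int:
    """Foreground pixel count of a projection (mm² at 1 mm spacing)."""
    return int(proj.pixels.sum())


def save_projection(proj: ProjectionImage, path: str | Path) -> None:
    """Export a projection as PNG (0/255) or 2D NIfTI, by extension."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".png"):
        from PIL import Image

        # image rows top-to-bottom = superior-to-inferior, columns = u
        img = (proj.pixels.T[::-1] * 255).astype(np.uint8)
        Image.fromarray(img, mode="L").save(path)
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(proj.pixel_spacing) + [1.0, 1.0])
        nib.save(nib.Nifti1Image(proj.pixels.astype(np.uint8), affine), path)
    else:
        raise ValueError(f"unsupported projection format: {path.name}")
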