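"""Reading, rasterizing and resampling 3D segmentation masks.

Canonical in-memory representation is :class:`LabelMask`: a binary voxel
grid indexed ``(x, y, z)`` where ``x`` runs left–right, ``y``
anterior–posterior and ``z`` inferior–superior — ``z`` is always the axial
(slice) axis, the plane clinicians contour on.  Voxel centers sit at
``origin + index * spacing`` (millimetres), 0-based indices.

NIfTI volumes are reoriented to closest-canonical (RAS+) on load so the
axis convention holds regardless of on-disk orientation; NRRD volumes go
through SimpleITK with the same normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "LabelMask",
    "ContourSet",
    "load_mask",
    "save_mask",
    "rasterize_contours",
    "resample_isotropic",
    "load_rtstruct_contours",
]


@dataclass
class LabelMask:
    """Binary 3D segmentation on a regular grid with physical spacing.

    Parameters
    ----------
    voxels
        3D array of {0, 1}, axis order (x, y, z); z is the axial slice axis.
    spacing
        Voxel size (sx, sy, sz) in mm; all components positive.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got {self.voxels.ndim}D")
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("voxels must contain only {0, 1}")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_foreground == 0

    def volume_mm3(self) -> float:
        """Foreground volume in mm³ (voxel count × voxel volume)."""
        return self.n_foreground * float(np.prod(self.spacing))


@dataclass
class ContourSet:
    """Closed planar polygons keyed by axial slice position (mm).

    ``slices`` maps a z position in mm to a list of polygons, each an
    (n, 2) array of (x, y) physical coordinates in mm.  Polygons must be
    simple (non-self-intersecting) with at least 3 vertices.
    """

    slices: Mapping[float, Sequence[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[float, list[np.ndarray]] = {}
        for z, polys in self.slices.items():
            checked = []
            for poly in polys:
                arr = np.asarray(poly, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                    raise ValueError(
                        f"polygon on slice z={z} must be (n>=3, 2), got {arr.shape}"
                    )
                if not _ShapelyPolygon(arr).is_valid:
                    raise ValueError(f"self-intersecting polygon on slice z={z}")
                checked.append(arr)
            cleaned[float(z)] = checked
        self.slices = cleaned


# ---------------------------------------------------------------------------
# File I/O


def load_mask(path: str | Path, label_value: int | None = None) -> LabelMask:
    """Load a 3D label volume as a binary :class:`LabelMask`.

    Supports NIfTI-1 (``.nii``/``.nii.gz``) and NRRD.  Multi-label volumes
    require an explicit ``label_value`` selecting the foreground; volumes
    already in {0, 1} may omit it.

    Raises
    ------
    ValueError
        If the file is not 3D, if ``label_value`` is missing for a
        multi-label volume, or if ``label_value`` does not occur.
    OSError / FileNotFoundError
        If the file cannot be read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.as_closest_canonical(nib.load(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif name.endswith(".nrrd"):
        # normalize axis permutations so z is axial; identity-direction
        # volumes pass through unchanged (SimpleITK's world frame is LPS)
        img = sitk.DICOMOrient(sitk.ReadImage(str(path)), "LPS")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D in {path.name}")

    data = np.asarray(data)
    labels = np.unique(data)
    if label_value is not None:
        if label_value not in labels:
            raise ValueError(f"label_value {label_value} not present (labels: {labels})")
        voxels = (data == label_value).astype(np.uint8)
    else:
        if not np.isin(labels, (0, 1)).all():
            raise ValueError(
                f"multi-label volume (labels {labels}); pass label_value explicitly"
            )
        voxels = (data > 0).astype(np.uint8)
    return LabelMask(voxels, spacing=spacing, origin=origin)


def save_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a mask as NIfTI-1 with a diagonal affine from spacing/origin."""
    path = Path(path)
    if not path.name.lower().endswith((".nii", ".nii.gz")):
        raise ValueError("save_mask writes NIfTI (.nii/.nii.gz) only")
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), path)


# ---------------------------------------------------------------------------
# Contour rasterization


def _points_in_polygon(poly: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even–odd (crossing-number) point-in-polygon test, vectorized.

    Half-open edge rule: a point on the lower/left boundary counts inside,
    on the upper/right outside, so abutting polygons tile without overlap.
    """
    inside = np.zeros(xs.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > ys) != (y2 > ys)
        if not crosses.any():
            continue
        x_int = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xs < x_int)
    return inside


def rasterize_contours(
    contours: ContourSet,
    grid_spacing: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LabelMask:
    """Fill planar contours into a binary voxel grid.

    Each polygon is filled by an even–odd point-in-polygon rule evaluated at
    voxel centers; polygons on the same slice are OR-combined.  All vertices
    must fall inside the physical extent of the grid (voxel cells, i.e.
    ``origin - spacing/2`` to ``origin + (shape - 1/2) * spacing``).
    """
    sx, sy, sz = (float(s) for s in grid_spacing)
    nx, ny, nz = grid_shape
    ox, oy, oz = (float(o) for o in origin)
    voxels = np.zeros((nx, ny, nz), dtype=np.uint8)
    # voxel-center coordinate grids for one axial plane
    xc = ox + np.arange(nx) * sx
    yc = oy + np.arange(ny) * sy
    XS, YS = np.meshgrid(xc, yc, indexing="ij")

    lo = (ox - sx / 2, oy - sy / 2, oz - sz / 2)
    hi = (ox + (nx - 0.5) * sx, oy + (ny - 0.5) * sy, oz + (nz - 0.5) * sz)

    for z_mm, polys in contours.slices.items():
        if not (lo[2] <= z_mm <= hi[2]):
            raise ValueError(f"contour slice z={z_mm} mm outside grid extent")
        k = int(round((z_mm - oz) / sz))
        k = min(max(k, 0), nz - 1)
        for poly in polys:
            if (
                poly[:, 0].min() < lo[0]
                or poly[:, 0].max() > hi[0]
                or poly[:, 1].min() < lo[1]
                or poly[:, 1].max() > hi[1]
            ):
                raise ValueError(f"contour on slice z={z_mm} mm outside grid extent")
            voxels[:, :, k] |= _points_in_polygon(poly, XS, YS)
    return LabelMask(voxels, spacing=(sx, sy, sz), origin=(ox, oy, oz))


# ---------------------------------------------------------------------------
# Resampling


def resample_isotropic(mask: LabelMask, target_spacing: float = 1.0) -> LabelMask:
    """Nearest-neighbour resampling of a binary mask to an isotropic grid.

    Voxels are treated as cells; the output grid tiles the same physical
    extent (within one voxel) and each output center maps to the input cell
    containing it.  Resampling at the mask's own spacing is the identity,
    and repeating at the same target is idempotent.
    """
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    t = float(target_spacing)
    voxels = mask.voxels
    index: list[np.ndarray] = []
    new_origin = []
    for ax, (n, s, o) in enumerate(zip(mask.shape, mask.spacing, mask.origin)):
        n_new = max(1, int(round(n * s / t)))
        # output cell centers at (i + 0.5)*t from the extent edge -> input cell
        src = np.floor((np.arange(n_new) + 0.5) * t / s).astype(int)
        index.append(np.clip(src, 0, n - 1))
        new_origin.append(o - s / 2 + t / 2)
    out = voxels[np.ix_(index[0], index[1], index[2])]
    return LabelMask(out, spacing=(t, t, t), origin=tuple(new_origin))


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT (optional input path)


def load_rtstruct_contours(path: str | Path, roi_name: str | None = None) -> ContourSet:
    """Extract one ROI's contours from a DICOM RT-STRUCT file.

    Contour points are taken in patient coordinates (mm); only the (x, y)
    in-plane components are kept, keyed by the contour's z position.  If
    ``roi_name`` is None the structure set must contain exactly one ROI.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    rois = {
        int(item.ROINumber): str(item.ROIName)
        for item in getattr(ds, "StructureSetROISequence", [])
    }
    if roi_name is None:
        if len(rois) != 1:
            raise ValueError(f"multiple ROIs present ({sorted(rois.values())}); pass roi_name")
        roi_name = next(iter(rois.values()))
    numbers = [num for num, nm in rois.items() if nm == roi_name]
    if not numbers:
        raise ValueError(f"ROI {roi_name!r} not found (available: {sorted(rois.values())})")
    target = numbers[0]

    slices: dict[float, list[np.ndarray]] = {}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        if int(roi_contour.ReferencedROINumber) != target:
            continue
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = round(float(np.median(pts[:, 2])), 3)
            slices.setdefault(z, []).append(pts[:, :2])
    if not slices:
        raise ValueError(f"ROI {roi_name!r} has no contour data")
    return ContourSet(slices)
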