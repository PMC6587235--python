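"""Volume geometry and the core in-memory containers.

Canonical array order is ``(slice, row, col)``:

* axis 0 — sagittal-oblique slice index, increasing lateral -> medial
  (glenoid level toward the medial scapular border);
* axis 1 — image row, increasing superior -> inferior;
* axis 2 — image column (anterior <-> posterior).

All spatial logic downstream (superior-inferior quartile bands,
lateral/intermediate/medial slice tertiles, per-slice areas) assumes this
order; readers are responsible for re-orienting input files into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VolumeGeometry",
    "FatWaterVolume",
    "LabelMask",
    "GeometryError",
    "HeaderError",
    "LabelError",
    "DEFAULT_LABEL_NAMES",
]

#: Rotator-cuff label convention: supraspinatus, combined infraspinatus/teres
#: minor (segmented as one muscle), subscapularis.
DEFAULT_LABEL_NAMES = {1: "SS", 2: "IS", 3: "SC"}


class GeometryError(ValueError):
    """Shapes or spacings of paired volumes are inconsistent."""


class HeaderError(ValueError):
    """A volume header carries missing, zero or negative spacing."""


class LabelError(ValueError):
    """A mask contains labels absent from the label map."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Physical geometry of a canonical ``(slice, row, col)`` volume.

    Parameters
    ----------
    in_plane_spacing : (float, float)
        Physical pixel size ``(row_mm, col_mm)`` within a slice.
    slice_thickness : float
        Slice spacing in mm along axis 0.
    n_slices : int
        Number of slices (extent of axis 0).
    axis_roles : dict
        Anatomical role of each array axis; fixed by the canonical order but
        stored explicitly so reports are self-describing.
    slice_order, row_order : str
        Direction of increasing index along axis 0 and axis 1.
    """

    in_plane_spacing: tuple[float, float]
    slice_thickness: float
    n_slices: int
    axis_roles: dict = field(
        default_factory=lambda: {
            "slice": "lateral-medial",
            "row": "superior-inferior",
            "col": "anterior-posterior",
        }
    )
    slice_order: str = "lateral_to_medial"
    row_order: str = "superior_to_inferior"

    def __post_init__(self):
        row_mm, col_mm = self.in_plane_spacing
        if not (row_mm > 0 and col_mm > 0 and self.slice_thickness > 0):
            raise HeaderError(
                f"spacings must be strictly positive, got "
                f"{self.in_plane_spacing} / {self.slice_thickness}"
            )
        if self.n_slices < 1:
            raise GeometryError("n_slices must be >= 1")
        roles = set(self.axis_roles)
        if roles != {"slice", "row", "col"}:
            raise GeometryError("axis_roles must map exactly slice/row/col")

    @property
    def voxel_volume_mm3(self) -> float:
        row_mm, col_mm = self.in_plane_spacing
        return row_mm * col_mm * self.slice_thickness

    def with_n_slices(self, n: int) -> "VolumeGeometry":
        return replace(self, n_slices=n)


def _check_array(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise GeometryError(f"{name} must be 3D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class FatWaterVolume:
    """Co-registered fat-only and water-only intensity volumes."""

    fat: np.ndarray
    water: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        self.fat = _check_array(self.fat, "fat")
        self.water = _check_array(self.water, "water")
        if self.fat.shape != self.water.shape:
            raise GeometryError(
                f"fat shape {self.fat.shape} != water shape {self.water.shape}"
            )
        if np.any(self.fat < 0) or np.any(self.water < 0):
            raise ValueError("fat/water intensities must be non-negative")
        if self.fat.shape[0] != self.geometry.n_slices:
            raise GeometryError(
                f"array has {self.fat.shape[0]} slices but geometry declares "
                f"{self.geometry.n_slices}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fat.shape


@dataclass
class LabelMask:
    """Multi-label muscle segmentation aligned to a FatWaterVolume grid.

    ``labels`` is an integer array with 0 = background; every nonzero value
    must appear in ``label_names``. Masks are filled ROIs, not contours.
    """

    labels: np.ndarray
    label_names: dict
    geometry: VolumeGeometry

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            if np.any(labels != np.round(labels)):
                raise LabelError("mask contains non-integer values")
            labels = labels.astype(np.int32)
        if np.any(labels < 0):
            raise LabelError("mask labels must be non-negative")
        present = set(np.unique(labels).tolist()) - {0}
        unknown = present - set(self.label_names)
        if unknown:
            raise LabelError(f"mask labels {sorted(unknown)} not in label map")
        if labels.shape[0] != self.geometry.n_slices:
            raise GeometryError(
                f"mask has {labels.shape[0]} slices but geometry declares "
                f"{self.geometry.n_slices}"
            )
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})

    def require_label(self, label: int) -> np.ndarray:
        """Boolean voxel mask for ``label``; raises if the ROI is empty."""
        roi = self.labels == label
        if not roi.any():
            raise LabelError(f"label {label} is absent from the mask")
        return roi


def check_same_grid(*objs) -> None:
    """Raise GeometryError unless all volumes/masks share shape and spacing."""
    shapes = {o.shape for o in objs}
    if len(shapes) > 1:
        raise GeometryError(f"grids differ: {sorted(shapes)}")
    geoms = [o.geometry for o in objs]
    g0 = geoms[0]
    for g in geoms[1:]:
        if (
            not np.allclose(g.in_plane_spacing, g0.in_plane_spacing)
            or not np.isclose(g.slice_thickness, g0.slice_thickness)
        ):
            raise GeometryError(
                f"voxel spacings differ: {g0.in_plane_spacing}/{g0.slice_thickness}"
                f" vs {g.in_plane_spacing}/{g.slice_thickness}"
            )
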