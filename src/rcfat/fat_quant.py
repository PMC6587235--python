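"""Voxelwise fat-fraction maps, whole-muscle %fat and 3D muscle volume.

The per-voxel fat fraction from a two-point Dixon fat/water pair is

    %fat = 100 * Fat / (Fat + Water)

undefined (NaN) where ``Fat + Water == 0``. Whole-muscle %fat supports two
estimators: ``slice_mean`` averages the per-slice ROI means over all slices
containing the muscle (the literal "average of all consecutive images"),
while ``voxel`` averages all labelled voxels and therefore weights slices by
their cross-sectional area. Muscle volume is the per-slice labelled area
times slice thickness, summed over slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import FatWaterVolume, LabelMask, VolumeGeometry, check_same_grid

__all__ = [
    "FatFractionMap",
    "MuscleSummary",
    "compute_fat_fraction",
    "muscle_mean_fat",
    "muscle_volume",
    "summarize_muscles",
]

log = logging.getLogger(__name__)

WEIGHTINGS = ("slice_mean", "voxel")


@dataclass
class FatFractionMap:
    """Voxelwise %fat in [0, 100]; NaN marks undefined (zero-signal) voxels."""

    ff: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        ff = np.asarray(self.ff, dtype=np.float64)
        defined = np.isfinite(ff)
        if defined.any() and (
            np.nanmin(ff[defined]) < -1e-9 or np.nanmax(ff[defined]) > 100 + 1e-9
        ):
            raise ValueError("defined fat-fraction values must lie in [0, 100]")
        self.ff = ff

    @property
    def shape(self):
        return self.ff.shape

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.ff)


@dataclass(frozen=True)
class MuscleSummary:
    label: int
    name: str
    mean_fat_pct_slice: float
    mean_fat_pct_voxel: float
    volume_cm3: float
    n_voxels: int
    n_slices: int
    n_undefined_excluded: int


def compute_fat_fraction(vol: FatWaterVolume) -> FatFractionMap:
    """Map a fat/water pair to %fat = 100*fat/(fat+water), NaN at zero signal."""
    denom = vol.fat + vol.water
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(denom > 0, 100.0 * vol.fat / np.where(denom > 0, denom, 1.0), np.nan)
    return FatFractionMap(ff=ff, geometry=vol.geometry)


def _roi_defined(ffmap: FatFractionMap, mask: LabelMask, label: int):
    """ROI voxels split into defined-ff and excluded (NaN) parts."""
    check_same_grid(ffmap, mask)
    roi = mask.require_label(label)
    defined = roi & ffmap.defined
    n_excluded = int(roi.sum() - defined.sum())
    if n_excluded:
        log.warning(
            "label %d: %d masked voxel(s) with undefined fat fraction excluded",
            label,
            n_excluded,
        )
    return roi, defined, n_excluded


def muscle_mean_fat(
    ffmap: FatFractionMap,
    mask: LabelMask,
    label: int,
    weighting: str = "slice_mean",
) -> float:
    """Whole-muscle mean %fat under the chosen slice or voxel weighting."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    _, defined, _ = _roi_defined(ffmap, mask, label)
    if not defined.any():
        raise ValueError(f"label {label}: no voxels with defined fat fraction")
    vals = ffmap.ff
    if weighting == "voxel":
        return float(vals[defined].mean())
    slice_means = [
        float(vals[s][defined[s]].mean())
        for s in range(defined.shape[0])
        if defined[s].any()
    ]
    return float(np.mean(slice_means))


def muscle_volume(mask: LabelMask, label: int) -> float:
    """3D muscle volume in cm^3: per-slice labelled area x slice thickness."""
    roi = mask.require_label(label)
    row_mm, col_mm = mask.geometry.in_plane_spacing
    per_slice_mm3 = roi.reshape(roi.shape[0], -1).sum(axis=1) * (
        row_mm * col_mm * mask.geometry.slice_thickness
    )
    return float(per_slice_mm3.sum() / 1000.0)


def summarize_muscles(
    ffmap: FatFractionMap, mask: LabelMask, labels=None
) -> list[MuscleSummary]:
    """Whole-muscle summary (both %fat weightings, volume, counts) per label."""
    out = []
    for label in labels if labels is not None else mask.present_labels():
        roi, defined, n_excl = _roi_defined(ffmap, mask, label)
        out.append(
            MuscleSummary(
                label=label,
                name=mask.label_names.get(label, str(label)),
                mean_fat_pct_slice=muscle_mean_fat(ffmap, mask, label, "slice_mean"),
                mean_fat_pct_voxel=muscle_mean_fat(ffmap, mask, label, "voxel"),
                volume_cm3=muscle_volume(mask, label),
                n_voxels=int(roi.sum()),
                n_slices=int(roi.reshape(roi.shape[0], -1).any(axis=1).sum()),
                n_undefined_excluded=n_excl,
            )
        )
    return out
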