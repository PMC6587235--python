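"""Spatial partitioning of a muscle ROI and regional statistics.

Two schemes:

* ``quartile_SI`` — four superior-to-inferior bands (Q1 superior-most). By
  default bands are computed per slice from that slice's occupied row extent,
  because a muscle's cross-section shifts superiorly/inferiorly from slice to
  slice; a ``global`` extent mode uses one 3D bounding box instead. With
  occupied rows [r_min, r_max] and band height h = (r_max - r_min + 1) / 4,
  the voxel at row r gets band min(4, floor((r - r_min)/h) + 1) — a
  deterministic rule whose band row-counts differ by at most one.

* ``tertile_ML`` — three contiguous groups of slices spanning the occupied
  slice range lateral -> medial (operationalising "from the glenoid to the
  medial border"): group sizes floor(n/3), remainder slices handed out one
  per group in a configurable order (default lateral first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fat_quant import WEIGHTINGS, FatFractionMap
from .geometry import LabelMask

__all__ = [
    "RegionPartition",
    "RegionalResult",
    "partition_quartiles",
    "partition_tertiles",
    "regional_stats",
    "QUARTILE_NAMES",
    "TERTILE_NAMES",
]

log = logging.getLogger(__name__)

QUARTILE_NAMES = {1: "Q1", 2: "Q2", 3: "Q3", 4: "Q4"}
TERTILE_NAMES = {1: "lateral", 2: "intermediate", 3: "medial"}

_REMAINDER_ORDERS = {
    "lateral": (1, 2, 3),
    "medial": (3, 2, 1),
    "intermediate": (2, 1, 3),
}


class DegenerateExtentError(ValueError):
    """Muscle spans too few slices for the requested partition."""


@dataclass
class RegionPartition:
    """Per-voxel region assignment for one muscle.

    ``region_of_voxel`` is a 3D int array: 0 outside the muscle, region id
    inside (quartiles 1..4 superior->inferior, tertiles 1..3 lateral->medial).
    """

    scheme: str
    label: int
    region_of_voxel: np.ndarray
    region_names: dict

    def __post_init__(self):
        ids = np.unique(self.region_of_voxel)
        unknown = set(ids.tolist()) - {0} - set(self.region_names)
        if unknown:
            raise ValueError(f"unknown region ids {sorted(unknown)}")

    def region_ids(self) -> list[int]:
        return sorted(self.region_names)

    def voxels_of(self, region_id: int) -> np.ndarray:
        return self.region_of_voxel == region_id


@dataclass(frozen=True)
class RegionRow:
    region: str
    mean_fat_pct_slice: float
    mean_fat_pct_voxel: float
    volume_cm3: float
    n_voxels: int


@dataclass
class RegionalResult:
    label: int
    scheme: str
    rows: list  # of RegionRow, region order


def partition_quartiles(
    mask: LabelMask, label: int, extent: str = "per_slice"
) -> RegionPartition:
    """Assign each muscle voxel to a superior-inferior quartile band."""
    if extent not in ("per_slice", "global"):
        raise ValueError("extent must be 'per_slice' or 'global'")
    roi = mask.require_label(label)
    out = np.zeros(roi.shape, dtype=np.int8)
    rows = np.arange(roi.shape[1])

    if extent == "global":
        occ = roi.any(axis=(0, 2))
        r_min, r_max = int(np.argmax(occ)), int(len(occ) - 1 - np.argmax(occ[::-1]))
        h = (r_max - r_min + 1) / 4.0
        band = np.minimum(4, ((rows - r_min) / h).astype(np.int64) + 1)
        for s in range(roi.shape[0]):
            if roi[s].any():
                out[s][roi[s]] = band[:, None].repeat(roi.shape[2], 1)[roi[s]]
        return RegionPartition("quartile_SI", label, out, dict(QUARTILE_NAMES))

    for s in range(roi.shape[0]):
        sl = roi[s]
        if not sl.any():
            continue
        occ = sl.any(axis=1)
        r_min = int(np.argmax(occ))
        r_max = int(len(occ) - 1 - np.argmax(occ[::-1]))
        h = (r_max - r_min + 1) / 4.0
        band = np.minimum(4, np.floor((rows - r_min) / h).astype(np.int64) + 1)
        out[s][sl] = band[:, None].repeat(sl.shape[1], 1)[sl]
    return RegionPartition("quartile_SI", label, out, dict(QUARTILE_NAMES))


def partition_tertiles(
    mask: LabelMask, label: int, remainder: str = "lateral"
) -> RegionPartition:
    """Split the occupied lateral->medial slice range into three slice groups."""
    if remainder not in _REMAINDER_ORDERS:
        raise ValueError(f"remainder must be one of {sorted(_REMAINDER_ORDERS)}")
    roi = mask.require_label(label)
    occ = roi.any(axis=(1, 2))
    first = int(np.argmax(occ))
    last = int(len(occ) - 1 - np.argmax(occ[::-1]))
    n = last - first + 1
    if n < 3:
        raise DegenerateExtentError(
            f"label {label} spans only {n} slice(s); tertiles need >= 3"
        )
    sizes = {g: n // 3 for g in (1, 2, 3)}
    for g in _REMAINDER_ORDERS[remainder][: n % 3]:
        sizes[g] += 1
    out = np.zeros(roi.shape, dtype=np.int8)
    start = first
    for g in (1, 2, 3):  # contiguous lateral -> medial
        stop = start + sizes[g]
        out[start:stop][roi[start:stop]] = g
        start = stop
    return RegionPartition("tertile_ML", label, out, dict(TERTILE_NAMES))


def regional_stats(
    ffmap: FatFractionMap,
    mask: LabelMask,
    partition: RegionPartition,
    weightings=WEIGHTINGS,
) -> RegionalResult:
    """Per-region mean %fat (both weightings) and volume.

    Regions with no defined-ff voxel are reported as NaN means with a warning
    rather than dropped, so the row structure stays fixed.
    """
    roi = mask.require_label(partition.label)
    if not np.array_equal(roi, partition.region_of_voxel > 0):
        raise ValueError("partition does not cover exactly this mask label")
    vox_mm3 = mask.geometry.voxel_volume_mm3
    defined = ffmap.defined
    rows = []
    for rid in partition.region_ids():
        rvox = partition.voxels_of(rid)
        n_vox = int(rvox.sum())
        rdef = rvox & defined
        if n_vox and not rdef.any():
            log.warning(
                "label %d region %s: no defined fat-fraction voxels",
                partition.label,
                partition.region_names[rid],
            )
        if rdef.any():
            voxel_mean = float(ffmap.ff[rdef].mean())
            slice_means = [
                float(ffmap.ff[s][rdef[s]].mean())
                for s in range(rdef.shape[0])
                if rdef[s].any()
            ]
            slice_mean = float(np.mean(slice_means))
        else:
            voxel_mean = slice_mean = float("nan")
        rows.append(
            RegionRow(
                region=partition.region_names[rid],
                mean_fat_pct_slice=slice_mean,
                mean_fat_pct_voxel=voxel_mean,
                volume_cm3=float(n_vox * vox_mm3 / 1000.0),
                n_voxels=n_vox,
            )
        )
    return RegionalResult(label=partition.label, scheme=partition.scheme, rows=rows)
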