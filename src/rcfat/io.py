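"""NIfTI reading/writing with canonical (slice, row, col) orientation.

Files written by this package store the array in canonical order with a
positive diagonal affine ``diag(slice_thickness, row_mm, col_mm, 1)``, so a
round trip is exact. Foreign files are first re-oriented with nibabel's
closest-canonical transform (which resolves the header orientation codes);
files whose headers do not encode the acquisition convention can be mapped
into canonical order with an explicit ``axes:`` override in a YAML config:

.. code-block:: yaml

    labels: {1: SS, 2: IS, 3: SC}
    axes:
      order: [2, 0, 1]        # file axes giving (slice, row, col)
      flip: [false, true, false]
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import (
    DEFAULT_LABEL_NAMES,
    FatWaterVolume,
    GeometryError,
    HeaderError,
    LabelMask,
    VolumeGeometry,
    check_same_grid,
)

__all__ = ["read_volume", "read_volume_pair", "write_volume", "load_config"]


def load_config(path) -> dict:
    """Load a YAML config with optional ``labels:`` and ``axes:`` sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "labels" in cfg:
        cfg["labels"] = {int(k): str(v) for k, v in cfg["labels"].items()}
    return cfg


def _apply_axes_override(data: np.ndarray, zooms, axes_cfg):
    order = axes_cfg.get("order", [0, 1, 2])
    if sorted(order) != [0, 1, 2]:
        raise GeometryError(f"axes order must be a permutation of 0..2: {order}")
    data = np.transpose(data, order)
    zooms = tuple(zooms[i] for i in order)
    for ax, do_flip in enumerate(axes_cfg.get("flip", [False] * 3)):
        if do_flip:
            data = np.flip(data, axis=ax)
    return data, zooms


def read_volume(path, axes_cfg: dict | None = None):
    """Read a single 3D NIfTI volume into canonical order.

    Returns ``(data, VolumeGeometry)``. Spacing comes from the header zooms;
    zero or missing spacing is a header error.
    """
    img = nib.load(str(path))
    if axes_cfg is None:
        img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if axes_cfg is not None:
        data, zooms = _apply_axes_override(data, zooms, axes_cfg)
    slice_mm, row_mm, col_mm = (float(z) for z in zooms)
    if min(slice_mm, row_mm, col_mm) <= 0:
        raise HeaderError(f"{path}: header spacing must be positive, got {zooms}")
    geom = VolumeGeometry(
        in_plane_spacing=(row_mm, col_mm),
        slice_thickness=slice_mm,
        n_slices=data.shape[0],
    )
    return np.ascontiguousarray(data), geom


def read_volume_pair(
    fat_path,
    water_path,
    mask_path,
    label_names: dict | None = None,
    axes_cfg: dict | None = None,
) -> tuple[FatWaterVolume, LabelMask]:
    """Read co-registered fat/water volumes plus the muscle label mask.

    All three grids must match in shape and spacing; mask labels must be
    covered by ``label_names`` (default: the rotator-cuff SS/IS/SC map).
    """
    fat, fat_geom = read_volume(fat_path, axes_cfg)
    water, water_geom = read_volume(water_path, axes_cfg)
    labels, mask_geom = read_volume(mask_path, axes_cfg)

    vol = FatWaterVolume(fat=fat, water=water, geometry=fat_geom)
    mask = LabelMask(
        labels=np.rint(labels).astype(np.int32),
        label_names=dict(label_names or DEFAULT_LABEL_NAMES),
        geometry=mask_geom,
    )
    # water grid re-checked explicitly: FatWaterVolume only compares arrays
    if water.shape != fat.shape:
        raise GeometryError(f"fat {fat.shape} vs water {water.shape}")
    check_same_grid(vol, mask)
    if not np.allclose(water_geom.in_plane_spacing, fat_geom.in_plane_spacing):
        raise GeometryError("fat/water in-plane spacings differ")
    return vol, mask


def write_volume(array: np.ndarray, geometry: VolumeGeometry, path) -> Path:
    """Write a canonical-order array as NIfTI; lossless for integer masks."""
    array = np.asarray(array)
    if array.ndim != 3:
        raise GeometryError(f"expected 3D array, got shape {array.shape}")
    if array.shape[0] != geometry.n_slices:
        raise GeometryError(
            f"array has {array.shape[0]} slices, geometry says {geometry.n_slices}"
        )
    row_mm, col_mm = geometry.in_plane_spacing
    affine = np.diag([geometry.slice_thickness, row_mm, col_mm, 1.0])
    if np.issubdtype(array.dtype, np.integer):
        out = array.astype(np.int32)
    else:
        out = array.astype(np.float64)
    img = nib.Nifti1Image(out, affine)
    img.header.set_zooms((geometry.slice_thickness, row_mm, col_mm))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
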