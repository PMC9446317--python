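"""Core 3D grid containers and NIfTI / label-table I/O.

All volumes are plain 3D numpy grids with an isotropic-or-not per-axis voxel
spacing in millimetres. Registration is an input contract: every volume that
enters a joint operation (segmentation, atlas overlap) must already live on the
same grid; the operations validate shape and spacing and refuse mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "LesionMask",
    "AtlasVolume",
    "load_volume",
    "load_mask",
    "load_atlas",
    "save_volume",
    "save_mask",
    "save_atlas",
]

HEMISPHERES = ("left", "right", "none")
TERRITORIES = ("left ICA", "right ICA", "basilar", "none")

_SPACING_RTOL = 1e-5


def _check_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing_mm must be 3 positive finite values, got {spacing_mm!r}")
    return spacing


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of finite scalars (e.g. an ADC map in mm²/s).
    spacing_mm
        Per-axis voxel edge length in millimetres.
    units
        Physical units of the scalar, informational only.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    units: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume data contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", _check_spacing(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class LesionMask:
    """A binary 3D lesion mask sharing the grid of its source volume."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got ndim={data.ndim}")
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be binary, found {uniq[:10]}")
            data = data.astype(bool)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", _check_spacing(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass(frozen=True)
class AtlasVolume:
    """Integer label volume plus the table mapping each label to its classes.

    ``label_table`` columns: ``label`` (int id), ``name``, ``hemisphere``
    (left/right/none), ``territory`` (left ICA / right ICA / basilar / none)
    and ``cortical`` (bool). Every nonzero voxel label must appear in the table.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    label_table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("atlas labels must be integers")
            labels = np.round(labels).astype(np.int32)
        table = self.label_table.copy()
        required = {"label", "name", "hemisphere", "territory", "cortical"}
        if missing := required - set(table.columns):
            raise ValueError(f"label table missing columns: {sorted(missing)}")
        table["label"] = table["label"].astype(int)
        table["cortical"] = table["cortical"].astype(bool)
        if table["label"].duplicated().any():
            raise ValueError("duplicate label ids in label table")
        bad_h = set(table["hemisphere"]) - set(HEMISPHERES)
        bad_t = set(table["territory"]) - set(TERRITORIES)
        if bad_h or bad_t:
            raise ValueError(f"unknown hemisphere/territory values: {bad_h | bad_t}")
        present = set(np.unique(labels)) - {0}
        declared = set(table["label"])
        if undeclared := present - declared:
            raise ValueError(f"voxel labels not in label table: {sorted(undeclared)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing_mm", _check_spacing(self.spacing_mm))
        object.__setattr__(self, "label_table", table)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def grids_match(a, b) -> bool:
    """True when two volumes share shape and spacing (within float tolerance)."""
    return a.shape == b.shape and np.allclose(a.spacing_mm, b.spacing_mm, rtol=_SPACING_RTOL)


def require_same_grid(a, b, what: str = "volumes") -> None:
    if not grids_match(a, b):
        raise ValueError(
            f"{what} are not on the same grid: shapes {a.shape} vs {b.shape}, "
            f"spacings {a.spacing_mm} vs {b.spacing_mm}"
        )


# ---------------------------------------------------------------------------
# NIfTI I/O: spacing travels in the affine diagonal / header zooms.
# ---------------------------------------------------------------------------

def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing_mm))
    nib.save(img, str(path))


def save_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing_mm))
    nib.save(img, str(path))


def save_atlas(atlas: AtlasVolume, nifti_path, table_path=None) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.spacing_mm))
    nib.save(img, str(nifti_path))
    if table_path is not None:
        atlas.label_table.to_csv(table_path, index=False)


def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_volume(path, units: str = "") -> ImageVolume:
    data, spacing = _load_nifti(path)
    return ImageVolume(data.astype(float), spacing, units=units)


def load_mask(path) -> LesionMask:
    data, spacing = _load_nifti(path)
    return LesionMask(data, spacing)


def load_atlas(nifti_path, table_path) -> AtlasVolume:
    data, spacing = _load_nifti(nifti_path)
    table = pd.read_csv(table_path)
    return AtlasVolume(np.round(data).astype(np.int32), spacing, table)


def brain_mask_like(volume: ImageVolume) -> LesionMask:
    """Whole-grid brain mask for volumes with no anatomical background."""
    return LesionMask(np.ones(volume.shape, dtype=bool), volume.spacing_mm)
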