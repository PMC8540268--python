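"""Volume and cohort-table input/output.

Volumes (SUV, HU) and binary masks travel as NIfTI-1 files; cohorts as
UTF-8 CSV with a header row. Geometry is axis-aligned, right-handed and
expressed in millimetres. Loaders validate consistency and refuse to
resample: a PET/HU pair with mismatched geometry is an error, never an
implicit interpolation, because the pipeline assumes scanner-co-registered
PET/CT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "ValidationError",
    "GridGeometry",
    "VolumePair",
    "BinaryMask",
    "read_volume_pair",
    "write_volume_pair",
    "read_mask",
    "write_mask",
    "read_cohort_table",
    "write_cohort_table",
    "with_measurable_nodes",
    "REQUIRED_COHORT_COLUMNS",
    "FEATURE_PREFIXES",
]


class GeometryError(ValueError):
    """Raised when grids disagree in shape, spacing or origin."""


class ValidationError(ValueError):
    """Raised when voxel values or table contents violate a contract."""


_GEOM_ATOL = 1e-3  # mm; float32 NIfTI headers round-trip well inside this


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned sampling grid: shape (voxels), spacing and origin in mm.

    The origin is the physical position of the centre of voxel (0, 0, 0),
    matching the NIfTI affine convention.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise GeometryError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def center_mm(self) -> np.ndarray:
        """Physical centre of the grid (midpoint of first/last voxel centres)."""
        return np.array(
            [self.origin_mm[a] + (self.shape[a] - 1) * self.spacing_mm[a] / 2.0 for a in range(3)]
        )

    def matches(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=_GEOM_ATOL)
            and np.allclose(self.origin_mm, other.origin_mm, atol=_GEOM_ATOL)
        )

    def require_match(self, other: "GridGeometry", what: str = "grids") -> None:
        if not self.matches(other):
            raise GeometryError(f"{what} have inconsistent geometry: {self} vs {other}")


def _geometry_from_nifti(img: nib.Nifti1Image) -> GridGeometry:
    aff = img.affine
    lin = aff[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise GeometryError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = np.diag(lin)
    if np.any(spacing <= 0):
        raise GeometryError("negative or zero spacing in affine; reorient to RAS first")
    return GridGeometry(tuple(img.shape[:3]), tuple(spacing), tuple(aff[:3, 3]))


@dataclass
class VolumePair:
    """Co-registered SUV (unitless, >= 0) and HU grids on one geometry."""

    suv: np.ndarray
    hu: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=np.float64)
        self.hu = np.asarray(self.hu, dtype=np.float64)
        if self.suv.shape != self.geometry.shape or self.hu.shape != self.geometry.shape:
            raise GeometryError(
                f"grid shapes {self.suv.shape}/{self.hu.shape} do not match "
                f"geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.suv)) or not np.all(np.isfinite(self.hu)):
            raise ValidationError("non-finite voxel values in volume pair")
        if np.any(self.suv < 0):
            raise ValidationError("negative SUV values are not physical")


@dataclass
class BinaryMask:
    """Boolean voxel mask sharing the geometry of its companion volume."""

    data: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.geometry.shape:
            raise GeometryError(
                f"mask shape {self.data.shape} does not match geometry {self.geometry.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.count * self.geometry.voxel_volume_ml


def write_volume_pair(pair: VolumePair, path_suv: str | Path, path_hu: str | Path) -> None:
    aff = pair.geometry.affine
    nib.save(nib.Nifti1Image(pair.suv.astype(np.float32), aff), str(path_suv))
    nib.save(nib.Nifti1Image(pair.hu.astype(np.float32), aff), str(path_hu))


def read_volume_pair(path_suv: str | Path, path_hu: str | Path) -> VolumePair:
    """Load an SUV/HU pair and validate that the grids are co-registered."""
    img_suv = nib.load(str(path_suv))
    img_hu = nib.load(str(path_hu))
    geom_suv = _geometry_from_nifti(img_suv)
    geom_hu = _geometry_from_nifti(img_hu)
    geom_suv.require_match(geom_hu, "SUV and HU volumes")
    suv = np.asarray(img_suv.get_fdata(), dtype=np.float64)
    hu = np.asarray(img_hu.get_fdata(), dtype=np.float64)
    return VolumePair(suv, hu, geom_suv)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), mask.geometry.affine),
        str(path),
    )


def read_mask(path: str | Path, companion: GridGeometry | None = None) -> BinaryMask:
    img = nib.load(str(path))
    geom = _geometry_from_nifti(img)
    if companion is not None:
        geom.require_match(companion, "mask and companion volume")
    data = np.asarray(img.get_fdata())
    bad = ~np.isin(data, (0, 1))
    if bad.any():
        raise ValidationError("mask file contains values other than 0/1")
    return BinaryMask(data > 0, geom)


# --- cohort tables ---------------------------------------------------------

REQUIRED_COHORT_COLUMNS = ("patient_id", "label_metastasis", "visual_read")

#: texture feature column families a cohort table may carry
FEATURE_PREFIXES = ("suv_", "glcm_", "ngldm_", "glrlm_", "glzlm_")

_OPTIONAL_FLOAT_COLUMNS = ("ln_suvmax", "tumor_size_cm")


def _validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id: {dup!r}")
    for col in ("label_metastasis", "visual_read"):
        if df[col].isna().any():
            raise ValidationError(f"column {col!r} must be non-missing")
        vals = set(pd.unique(df[col]))
        if not vals <= {0, 1, True, False}:
            raise ValidationError(f"column {col!r} must be binary 0/1, got values {sorted(vals)}")
        df[col] = df[col].astype(int)
    for col in _OPTIONAL_FLOAT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a per-patient cohort CSV; missing ln_suvmax stays missing (NaN)."""
    df = pd.read_csv(path)
    return _validate_cohort(df)


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    _validate_cohort(df.copy())
    df.to_csv(path, index=False)


def with_measurable_nodes(df: pd.DataFrame) -> pd.DataFrame:
    """Rows with a measured axillary-node SUVmax (analysis subset for that test)."""
    if "ln_suvmax" not in df.columns:
        raise ValidationError("cohort table has no ln_suvmax column")
    return df.loc[df["ln_suvmax"].notna()]
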