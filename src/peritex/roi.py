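"""Peritumoral and contralateral adipose-tissue ROI construction.

The peritumoral region is the fat within a fixed physical distance
(default 10 mm) of the tumour margin: a spheroid tumour VOI is expanded by
a Euclidean distance transform computed in millimetres on the native
(possibly anisotropic) grid, then restricted to voxels whose CT
attenuation falls in the adipose window (default -200..-50 HU, both bounds
inclusive). A mirrored VOI across the midsagittal plane provides the
contralateral reference region. Tracer spill-in from the hot tumour is
suppressed by a configurable guard distance and optional SUV cap, standing
in for the manual scrutiny a human reader would apply.

All membership tests are voxel-centre tests; no partial-volume fractions
and no resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask, GeometryError, GridGeometry, ValidationError, VolumePair

__all__ = [
    "ATWindow",
    "ROISet",
    "spheroid_voi",
    "margin_shell",
    "at_mask",
    "exclude_spillover",
    "mirror_contralateral",
    "check_at_volume",
    "suv_max",
    "build_roi_set",
    "distance_to_mask_mm",
]


@dataclass(frozen=True)
class ATWindow:
    """Adipose-tissue CT attenuation window, inclusive at both bounds."""

    hu_low: float = -200.0
    hu_high: float = -50.0

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValidationError(f"hu_low must be < hu_high, got [{self.hu_low}, {self.hu_high}]")


@dataclass
class ROISet:
    """The four masks of one patient plus adipose volumes in ml."""

    tumor_mask: BinaryMask
    peritumoral_voi: BinaryMask
    peritumoral_at: BinaryMask
    contralateral_voi: BinaryMask
    contralateral_at: BinaryMask
    peritumoral_at_ml: float
    contralateral_at_ml: float


def spheroid_voi(
    center_mm: tuple[float, float, float],
    radii_mm: tuple[float, float, float],
    geometry: GridGeometry,
) -> BinaryMask:
    """Voxel-centre spheroid: included iff sum(((x-c)/r)^2) <= 1.

    A zero radius degenerates to an exact coordinate match along that axis,
    so radii -> 0 yields the single voxel at the centre.
    """
    center = np.asarray(center_mm, dtype=float)
    radii = np.asarray(radii_mm, dtype=float)
    if np.any(radii < 0):
        raise ValidationError(f"radii must be >= 0, got {radii_mm}")
    for a in range(3):
        lo = geometry.origin_mm[a]
        hi = geometry.origin_mm[a] + (geometry.shape[a] - 1) * geometry.spacing_mm[a]
        if center[a] - radii[a] < lo - 1e-9 or center[a] + radii[a] > hi + 1e-9:
            raise GeometryError(
                f"spheroid (center {center_mm}, radii {radii_mm}) exits grid along axis {a}"
            )
    terms = []
    for a in range(3):
        d = geometry.axis_centers_mm(a) - center[a]
        r = radii[a] if radii[a] > 0 else 1e-12
        terms.append((d / r) ** 2)
    q = (
        terms[0][:, None, None]
        + terms[1][None, :, None]
        + terms[2][None, None, :]
    )
    return BinaryMask(q <= 1.0 + 1e-12, geometry)


def distance_to_mask_mm(mask: BinaryMask) -> np.ndarray:
    """Euclidean distance (mm) from each voxel centre to the nearest mask voxel."""
    if mask.count == 0:
        raise ValidationError("distance to an empty mask is undefined")
    return ndimage.distance_transform_edt(~mask.data, sampling=mask.geometry.spacing_mm)


def margin_shell(tumor_mask: BinaryMask, distance_mm: float = 10.0) -> BinaryMask:
    """Voxels outside the tumour within `distance_mm` of its voxel set."""
    if distance_mm < 0:
        raise ValidationError("distance_mm must be >= 0")
    dist = distance_to_mask_mm(tumor_mask)
    shell = (~tumor_mask.data) & (dist <= distance_mm + 1e-9) & (dist > 0)
    return BinaryMask(shell, tumor_mask.geometry)


def at_mask(voi: BinaryMask, hu_grid: np.ndarray, window: ATWindow = ATWindow()) -> BinaryMask:
    """Restrict a VOI to the adipose HU window (inclusive bounds)."""
    hu = np.asarray(hu_grid)
    if hu.shape != voi.geometry.shape:
        raise GeometryError(f"HU grid shape {hu.shape} does not match VOI {voi.geometry.shape}")
    sel = voi.data & (hu >= window.hu_low) & (hu <= window.hu_high)
    return BinaryMask(sel, voi.geometry)


def exclude_spillover(
    at: BinaryMask,
    tumor_mask: BinaryMask,
    guard_mm: float = 0.0,
    suv_grid: np.ndarray | None = None,
    suv_cap: float | None = None,
) -> BinaryMask:
    """Drop AT voxels within `guard_mm` of the tumour and, optionally, hot voxels.

    guard_mm = 0 keeps every non-tumour voxel (distances outside the tumour
    are strictly positive); the tumour voxels themselves are always removed.
    """
    at.geometry.require_match(tumor_mask.geometry, "AT and tumor masks")
    if guard_mm < 0:
        raise ValidationError("guard_mm must be >= 0")
    keep = at.data & ~tumor_mask.data
    if guard_mm > 0:
        dist = distance_to_mask_mm(tumor_mask)
        keep &= dist > guard_mm + 1e-9
    if suv_cap is not None:
        if suv_grid is None:
            raise ValidationError("suv_cap requires the SUV grid")
        suv = np.asarray(suv_grid)
        if suv.shape != at.geometry.shape:
            raise GeometryError("SUV grid shape does not match mask")
        keep &= suv <= suv_cap
    return BinaryMask(keep, at.geometry)


def mirror_contralateral(
    voi: BinaryMask,
    plane_mm: float | None = None,
    axis: int = 0,
) -> BinaryMask:
    """Reflect a VOI across the left-right plane `x = plane_mm`.

    The plane must map voxel centres onto voxel centres (it does whenever it
    sits on a voxel centre or halfway between two), so the reflection is an
    exact involution and preserves the voxel count. Default plane: the grid's
    physical centre along `axis`.
    """
    geom = voi.geometry
    if plane_mm is None:
        plane_mm = float(geom.center_mm()[axis])
    s = geom.spacing_mm[axis]
    # reflected index i' = K - i with K = 2*(plane - origin)/spacing
    k = 2.0 * (plane_mm - geom.origin_mm[axis]) / s
    k_int = round(k)
    if abs(k - k_int) > 1e-6:
        raise GeometryError(
            f"mirror plane at {plane_mm} mm does not map voxel centres onto voxel centres"
        )
    idx = np.argwhere(voi.data)
    if idx.size == 0:
        return BinaryMask(np.zeros(geom.shape, bool), geom)
    mirrored = idx.copy()
    mirrored[:, axis] = k_int - idx[:, axis]
    if mirrored[:, axis].min() < 0 or mirrored[:, axis].max() >= geom.shape[axis]:
        raise GeometryError("mirrored VOI exits the grid")
    out = np.zeros(geom.shape, bool)
    out[tuple(mirrored.T)] = True
    return BinaryMask(out, geom)


def check_at_volume(mask: BinaryMask, min_ml: float = 1.0) -> tuple[bool, float]:
    """Adipose volume in ml and whether it meets the minimum for texture analysis."""
    vol = mask.volume_ml
    return vol >= min_ml, vol


def suv_max(mask: BinaryMask, suv_grid: np.ndarray) -> float:
    suv = np.asarray(suv_grid)
    if suv.shape != mask.geometry.shape:
        raise GeometryError("SUV grid shape does not match mask")
    if mask.count == 0:
        raise ValidationError("SUVmax of an empty mask is undefined")
    return float(suv[mask.data].max())


def build_roi_set(
    pair: VolumePair,
    tumor_mask: BinaryMask,
    window: ATWindow = ATWindow(),
    margin_mm: float = 10.0,
    guard_mm: float | None = None,
    suv_cap: float | None = None,
    mirror_plane_mm: float | None = None,
    mirror_axis: int = 0,
) -> ROISet:
    """Full §-style ROI construction: tumour VOI + margin, HU windowing,
    spill-over guard, and geometric contralateral mirror.

    `guard_mm` defaults to one voxel diagonal, a deterministic surrogate for
    the manual exclusion of tumour spill-in.
    """
    pair.geometry.require_match(tumor_mask.geometry, "volume pair and tumor mask")
    if guard_mm is None:
        guard_mm = float(np.linalg.norm(pair.geometry.spacing_mm))
    shell = margin_shell(tumor_mask, margin_mm)
    peritumoral_voi = BinaryMask(shell.data | tumor_mask.data, pair.geometry)
    peri_at = at_mask(shell, pair.hu, window)
    peri_at = exclude_spillover(peri_at, tumor_mask, guard_mm, pair.suv, suv_cap)
    contra_voi = mirror_contralateral(peritumoral_voi, mirror_plane_mm, mirror_axis)
    contra_at = at_mask(contra_voi, pair.hu, window)
    return ROISet(
        tumor_mask=tumor_mask,
        peritumoral_voi=peritumoral_voi,
        peritumoral_at=peri_at,
        contralateral_voi=contra_voi,
        contralateral_at=contra_at,
        peritumoral_at_ml=peri_at.volume_ml,
        contralateral_at_ml=contra_at.volume_ml,
    )
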