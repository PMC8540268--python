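"""Synthetic PET/CT phantoms and patient cohorts.

No patient images or tables are distributed with the analysis this package
reimplements, so every downstream stage is exercised on synthetic data with
the same statistical structure:

* ``generate_phantom`` builds a paired SUV/HU volume containing two
  HU-banded "breast" slabs of adipose tissue symmetric about the
  midsagittal plane, a spheroid tumour of elevated uptake inside one of
  them, and a spatially correlated SUV noise field in the fat whose
  amplitude is set by a single ``heterogeneity`` dial (a white Gaussian
  field smoothed with a 1-voxel-sigma kernel, scaled to amplitude
  ``heterogeneity * at_suv_sd``).

* ``simulate_feature_cohort`` draws a per-patient texture feature (GLCM
  entropy by default) from class-conditional normals parameterised by the
  four visual-read outcome groups (true-negative, false-negative,
  true-positive, false-positive), which is how the source cohort's group
  statistics are reported; metastatic = TP + FN, visually positive =
  TP + FP.

* ``simulate_imaging_cohort`` builds a labelled set of phantoms where the
  metastatic class receives an additive heterogeneity offset, for
  end-to-end signal-recovery tests.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import BinaryMask, GridGeometry, ValidationError, VolumePair
from .roi import spheroid_voi

__all__ = [
    "PhantomSpec",
    "Phantom",
    "CohortSimSpec",
    "GROUPS",
    "generate_phantom",
    "simulate_feature_cohort",
    "simulate_imaging_cohort",
]

#: visual-read outcome groups, in the order used everywhere
GROUPS = ("TN", "FN", "TP", "FP")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of one digital phantom.

    Defaults give a 120 x 120 x 84 mm grid at 3 mm isotropic spacing with a
    breast slab on each side, an 8 mm-radius tumour in the right breast, and
    adipose SUV levels chosen so the extracted GLCM entropy of peritumoral
    fat falls in the low single digits at the default 64-level / [0, 20] SUV
    discretisation, matching the dynamic range reported for real adipose
    tissue. Absolute SUV/HU levels of fat are free parameters of the
    simulation, not literature constants.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 28)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tumor_center_mm: tuple[float, float, float] = (30.0, 58.5, 40.5)
    tumor_radii_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    tumor_suv_mean: float = 6.0
    tumor_suv_sd: float = 1.0
    at_hu_mean: float = -100.0
    at_hu_sd: float = 30.0
    at_suv_mean: float = 0.8
    at_suv_sd: float = 0.25
    heterogeneity: float = 1.0
    background_hu_mean: float = 30.0
    background_suv_mean: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValidationError("tumor radii must be > 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing must be > 0")
        if self.heterogeneity < 0:
            raise ValidationError("heterogeneity must be >= 0")
        if self.at_suv_sd < 0 or self.tumor_suv_sd < 0 or self.at_hu_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.tumor_suv_mean < self.at_suv_mean:
            raise ValidationError("tumor SUV mean must be >= adipose SUV mean")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.grid_shape, self.spacing_mm)


@dataclass
class Phantom:
    """A generated volume pair with its ground-truth masks."""

    pair: VolumePair
    tumor_mask: BinaryMask
    at_mask: BinaryMask  # true adipose voxels (both breasts, inside HU window)
    breast_mask: BinaryMask  # slab regions before HU windowing


# breast slabs as fractions of the physical grid extent per axis
_SLAB_X = ((0.05, 0.45), (0.55, 0.95))
_SLAB_YZ = (0.08, 0.92)


def _slab_masks(geom: GridGeometry) -> np.ndarray:
    ext = [geom.axis_centers_mm(a) for a in range(3)]
    span = [ext[a][-1] - ext[a][0] for a in range(3)]
    inside_yz = np.ones(geom.shape, bool)
    for a in (1, 2):
        lo = ext[a][0] + _SLAB_YZ[0] * span[a]
        hi = ext[a][0] + _SLAB_YZ[1] * span[a]
        coord = ext[a]
        sel = (coord >= lo) & (coord <= hi)
        shape = [1, 1, 1]
        shape[a] = geom.shape[a]
        inside_yz &= sel.reshape(shape)
    slabs = np.zeros(geom.shape, bool)
    for flo, fhi in _SLAB_X:
        lo = ext[0][0] + flo * span[0]
        hi = ext[0][0] + fhi * span[0]
        sel = (ext[0] >= lo) & (ext[0] <= hi)
        slabs |= sel[:, None, None] & inside_yz
    return slabs


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one phantom; identical spec + seed gives bit-identical volumes.

    Raises a geometry error if the tumour spheroid does not fit inside the
    grid. With ``heterogeneity = 0`` and ``at_suv_sd = 0`` every adipose SUV
    voxel is exactly ``at_suv_mean``.
    """
    geom = spec.geometry
    tumor = spheroid_voi(spec.tumor_center_mm, spec.tumor_radii_mm, geom)  # GeometryError if outside
    breast = _slab_masks(geom) & ~tumor.data
    rng = np.random.default_rng(spec.rng_seed)

    hu = rng.normal(spec.background_hu_mean, 10.0, geom.shape)
    hu[breast] = rng.normal(spec.at_hu_mean, spec.at_hu_sd, int(breast.sum()))
    hu[tumor.data] = rng.normal(40.0, 10.0, tumor.count)

    suv = rng.normal(spec.background_suv_mean, 0.05, geom.shape)
    suv[breast] = rng.normal(spec.at_suv_mean, spec.at_suv_sd, int(breast.sum()))
    # spatially correlated heterogeneity: smoothed unit-variance Gaussian field
    if spec.heterogeneity > 0 and spec.at_suv_sd > 0:
        white = rng.standard_normal(geom.shape)
        fieldv = ndimage.gaussian_filter(white, sigma=1.0)
        fieldv /= fieldv.std()
        suv[breast] += spec.heterogeneity * spec.at_suv_sd * fieldv[breast]
    suv[tumor.data] = rng.normal(spec.tumor_suv_mean, spec.tumor_suv_sd, tumor.count)
    np.clip(suv, 0.0, None, out=suv)

    at_true = breast & (hu >= -200.0) & (hu <= -50.0)
    pair = VolumePair(suv, hu, geom)
    return Phantom(
        pair=pair,
        tumor_mask=tumor,
        at_mask=BinaryMask(at_true, geom),
        breast_mask=BinaryMask(breast, geom),
    )


# --- feature-level cohort simulation ----------------------------------------


@dataclass(frozen=True)
class CohortSimSpec:
    """Class-conditional simulation of one texture feature over the four
    visual-read groups (TN, FN, TP, FP).

    Defaults reproduce the reported group structure of the source cohort:
    sizes 194/55/64/13 and GLCM-entropy normals (2.79, 0.78), (3.48, 0.72),
    (4.05, 0.76), (2.79, 0.55). Node SUVmax is drawn log-normally per
    metastasis class around configurable medians (only a cohort median is
    reported, so these are stated defaults, not reproduced truth).
    """

    group_sizes: tuple[int, int, int, int] = (194, 55, 64, 13)
    group_feature_means: tuple[float, float, float, float] = (2.79, 3.48, 4.05, 2.79)
    group_feature_sds: tuple[float, float, float, float] = (0.78, 0.72, 0.76, 0.55)
    feature_name: str = "glcm_entropy"
    # (median, log-sd) of LN SUVmax for non-metastatic / metastatic patients
    ln_suvmax_params: tuple[tuple[float, float], tuple[float, float]] = ((0.9, 0.45), (2.2, 0.8))
    ln_suvmax_missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes):
            raise ValidationError("group sizes must be >= 0")
        if any(s <= 0 for s in self.group_feature_sds):
            raise ValidationError("group feature SDs must be > 0")
        if not 0 <= self.ln_suvmax_missing_rate < 1:
            raise ValidationError("ln_suvmax_missing_rate must be in [0, 1)")


_METASTATIC = {"TP": 1, "FN": 1, "TN": 0, "FP": 0}
_VISUAL_POS = {"TP": 1, "FP": 1, "TN": 0, "FN": 0}


def simulate_feature_cohort(spec: CohortSimSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per patient: group, labels, LN SUVmax and the simulated feature.

    Metastasis label is 1 exactly for the TP and FN groups; the visual read
    is positive exactly for TP and FP.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    rows = []
    pid = 0
    for g, n, mu, sd in zip(GROUPS, spec.group_sizes, spec.group_feature_means,
                            spec.group_feature_sds):
        vals = rng.normal(mu, sd, n)
        met = _METASTATIC[g]
        med, lsd = spec.ln_suvmax_params[met]
        ln = np.exp(rng.normal(np.log(med), lsd, n))
        if spec.ln_suvmax_missing_rate > 0:
            ln[rng.random(n) < spec.ln_suvmax_missing_rate] = np.nan
        for v, s in zip(vals, ln):
            pid += 1
            rows.append({
                "patient_id": f"P{pid:04d}",
                "group": g,
                "label_metastasis": met,
                "visual_read": _VISUAL_POS[g],
                "ln_suvmax": s,
                spec.feature_name: v,
            })
    return pd.DataFrame(rows)


def simulate_imaging_cohort(
    n: int,
    phantom_base: PhantomSpec,
    effect: float,
    prevalence: float,
    seed: int,
) -> list[tuple[Phantom, int]]:
    """`n` labelled phantoms; metastatic patients (fraction `prevalence`,
    rounded) receive `heterogeneity + effect`."""
    if n <= 0:
        raise ValidationError("cohort size must be > 0")
    if not 0 < prevalence < 1:
        raise ValidationError("prevalence must be in (0, 1)")
    if effect < 0:
        raise ValidationError("effect must be >= 0")
    n_pos = int(round(n * prevalence))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    out = []
    for label, s in zip(labels, seeds):
        het = phantom_base.heterogeneity + (effect if label else 0.0)
        spec = replace(phantom_base, heterogeneity=het, rng_seed=int(s))
        out.append((generate_phantom(spec), int(label)))
    return out
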