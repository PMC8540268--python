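"""Grey-level texture features of an SUV field over a voxel mask.

Implements the 38-feature panel used for PET adipose-tissue radiomics:

* 7 first-order features of the SUV distribution (min, max, mean, SD,
  skewness, kurtosis, histogram entropy),
* 6 grey-level co-occurrence matrix (GLCM) features,
* 3 neighbourhood grey-level difference (NGLDM) features
  (coarseness, contrast, busyness),
* 11 grey-level run-length matrix (GLRLM) features,
* 11 grey-level zone-length matrix (GLZLM, a.k.a. GLSZM) features.

Conventions (all configurable where meaningful):

* SUV values are discretised to Ng levels (default 64) over an absolute
  SUV window (default [0, 20]) before any matrix is built.
* GLCM/GLRLM use the 13 unique 3D directions at Chebyshev distance 1;
  per-direction matrices are summed before normalisation/feature
  computation (a single pooled matrix, symmetric for the GLCM).
* Zones and NGLDM neighbourhoods are 26-connected; neighbours outside the
  mask are excluded, never zero-padded.
* Entropies use log base 2.
* Degenerate statistics (zero variance, single grey level) yield explicit
  NaN flags rather than silent zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .io import BinaryMask, ValidationError, VolumePair

__all__ = [
    "DiscretizationSpec",
    "discretize",
    "discretize_grid",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "ngldm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glzlm_matrix",
    "glzlm_features",
    "extract_all",
    "FeatureVector",
    "FEATURE_NAMES",
    "DIRECTIONS_13",
    "OFFSETS_26",
]

#: 13 unique direction vectors of the 26-neighbourhood (one per +/- pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

#: all 26 neighbour offsets
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)

FEATURE_NAMES: tuple[str, ...] = (
    "suv_min", "suv_max", "suv_mean", "suv_sd",
    "suv_skewness", "suv_kurtosis", "suv_hist_entropy",
    "glcm_homogeneity", "glcm_energy", "glcm_contrast",
    "glcm_correlation", "glcm_entropy", "glcm_dissimilarity",
    "ngldm_coarseness", "ngldm_contrast", "ngldm_busyness",
    "glrlm_sre", "glrlm_lre", "glrlm_lgre", "glrlm_hgre",
    "glrlm_srlge", "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge",
    "glrlm_glnu", "glrlm_rlnu", "glrlm_rp",
    "glzlm_sze", "glzlm_lze", "glzlm_lgze", "glzlm_hgze",
    "glzlm_szlge", "glzlm_szhge", "glzlm_lzlge", "glzlm_lzhge",
    "glzlm_glnu", "glzlm_zlnu", "glzlm_zp",
)


@dataclass(frozen=True)
class DiscretizationSpec:
    """Grey-level discretisation: Ng levels over absolute or ROI min-max bounds.

    ``mode="absolute"`` maps the fixed SUV window ``bounds`` onto levels
    1..Ng with values clamped into the window; ``mode="roi"`` maps the
    observed [min, max] of the ROI onto 1..Ng (max -> Ng).
    """

    n_levels: int = 64
    mode: str = "absolute"
    bounds: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2")
        if self.mode not in ("absolute", "roi"):
            raise ValidationError(f"unknown discretisation mode {self.mode!r}")
        if self.bounds[1] <= self.bounds[0]:
            raise ValidationError(f"bounds must satisfy lo < hi, got {self.bounds}")

    def provenance(self) -> dict:
        return {
            "disc_n_levels": self.n_levels,
            "disc_mode": self.mode,
            "disc_lo": self.bounds[0],
            "disc_hi": self.bounds[1],
        }


def discretize(values: np.ndarray, spec: DiscretizationSpec = DiscretizationSpec()) -> np.ndarray:
    """Map SUV values onto integer grey levels 1..Ng.

    level = clamp(floor((v - lo) / (hi - lo) * Ng) + 1, 1, Ng); a value
    exactly at the upper bound lands in level Ng.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("cannot discretise an empty ROI")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite SUV values")
    ng = spec.n_levels
    if spec.mode == "absolute":
        lo, hi = spec.bounds
    else:
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:  # constant ROI: single level
            return np.ones(v.shape, dtype=np.int64)
    lev = np.floor((v - lo) / (hi - lo) * ng).astype(np.int64) + 1
    return np.clip(lev, 1, ng)


def discretize_grid(
    suv: np.ndarray, mask: BinaryMask, spec: DiscretizationSpec = DiscretizationSpec()
) -> np.ndarray:
    """Discretised level grid: 1..Ng inside the mask, 0 outside."""
    out = np.zeros(mask.geometry.shape, dtype=np.int64)
    out[mask.data] = discretize(np.asarray(suv)[mask.data], spec)
    return out


# --- shifting helpers -------------------------------------------------------


def _shift_slices(shape, d):
    """Slices (src, dst) with dst = src + d, both in bounds."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step >= 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


# --- first order ------------------------------------------------------------


def first_order_features(values: np.ndarray, levels: np.ndarray, n_levels: int) -> dict:
    """Min/max/mean/SD, standardised 3rd/4th moments, and the entropy (bits)
    of the Ng-bin discretised histogram.

    SD is the population SD; kurtosis is the plain standardised 4th moment
    (3 for a normal distribution). Zero variance leaves skewness/kurtosis
    NaN with a warning; the histogram entropy of a constant ROI is 0.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValidationError("first-order features need >= 2 voxels")
    mean = float(v.mean())
    sd = float(v.std())
    if sd > 0:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        warnings.warn("zero SUV variance: skewness/kurtosis undefined", RuntimeWarning)
        skew = kurt = float("nan")
    counts = np.bincount(np.asarray(levels), minlength=n_levels + 1)[1:]
    q = counts[counts > 0] / v.size
    entropy = float(-(q * np.log2(q)).sum())
    return {
        "suv_min": float(v.min()),
        "suv_max": float(v.max()),
        "suv_mean": mean,
        "suv_sd": sd,
        "suv_skewness": skew,
        "suv_kurtosis": kurt,
        "suv_hist_entropy": entropy,
    }


# --- GLCM -------------------------------------------------------------------


def glcm_matrix(
    level_grid: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions=DIRECTIONS_13,
) -> np.ndarray:
    """Pooled symmetric co-occurrence probability matrix at distance 1.

    Voxel pairs with both endpoints in the mask are counted for every
    direction, accumulated in both (i, j) and (j, i), summed over
    directions, and normalised to a probability matrix.
    """
    L = np.asarray(level_grid)
    m = np.asarray(mask, bool)
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for d in directions:
        src, dst = _shift_slices(L.shape, d)
        sel = m[src] & m[dst]
        if not sel.any():
            continue
        i = L[src][sel] - 1
        j = L[dst][sel] - 1
        counts += np.bincount(i * n_levels + j, minlength=n_levels**2).reshape(
            n_levels, n_levels
        )
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValidationError("no valid voxel pairs for the GLCM (isolated voxels?)")
    return counts / total


def glcm_features(p: np.ndarray) -> dict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    absdiff = np.abs(ii - jj)
    pi = p.sum(axis=1)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    if var > 0:
        corr = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    else:
        corr = float("nan")  # single grey level: correlation undefined
    return {
        "glcm_homogeneity": float((p / (1.0 + absdiff)).sum()),
        "glcm_energy": float((p**2).sum()),
        "glcm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "glcm_correlation": corr,
        "glcm_entropy": entropy,
        "glcm_dissimilarity": float((absdiff * p).sum()),
    }


# --- NGLDM ------------------------------------------------------------------


def ngldm_features(level_grid: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    """Coarseness, contrast and busyness from level-vs-neighbourhood differences.

    For each masked voxel the mean grey level of its in-mask 26-neighbours is
    computed (voxels with no in-mask neighbour are dropped); s_i accumulates
    |level - neighbourhood mean| per level. Constant ROIs give contrast 0 and
    busyness 0 (degenerate 0/0 convention) and infinite coarseness.
    """
    L = np.asarray(level_grid)
    m = np.asarray(mask, bool)
    if m.sum() < 2:
        raise ValidationError("NGLDM needs >= 2 voxels")
    vals = np.where(m, L, 0).astype(np.float64)
    mf = m.astype(np.float64)
    nsum = np.zeros(L.shape)
    ncnt = np.zeros(L.shape)
    for d in OFFSETS_26:
        src, dst = _shift_slices(L.shape, d)
        nsum[src] += vals[dst]
        ncnt[src] += mf[dst]
    valid = m & (ncnt > 0)
    n_valid = int(valid.sum())
    abar = nsum[valid] / ncnt[valid]
    lev = L[valid]
    diff = np.abs(lev - abar)
    n_i = np.bincount(lev, minlength=n_levels + 1)[1:].astype(np.float64)
    s_i = np.bincount(lev, weights=diff, minlength=n_levels + 1)[1:]
    p_i = n_i / n_valid
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else float("inf")
    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        di = (i[:, None] - i[None, :]) ** 2
        contrast = float((pi_ * pj_ * di).sum() / (ngp * (ngp - 1)) * s_i.sum() / n_valid)
        ipi = i * p_i
        a, b = np.meshgrid(ipi[present], ipi[present], indexing="ij")
        denom = float(np.abs(a - b).sum())
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {
        "ngldm_coarseness": coarseness,
        "ngldm_contrast": contrast,
        "ngldm_busyness": busyness,
    }


# --- GLRLM ------------------------------------------------------------------


def glrlm_matrix(
    level_grid: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions=DIRECTIONS_13,
) -> np.ndarray:
    """Run-length counts r[i, l] summed over directions.

    A run is a maximal collinear sequence of in-mask voxels sharing one grey
    level. Column l (0-based l-1) holds runs of length l; the width is the
    largest grid extent. Sum over l of l*r equals (#directions * #voxels).
    """
    L = np.asarray(level_grid)
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValidationError("empty mask")
    rmax = max(L.shape)
    R = np.zeros((n_levels, rmax), dtype=np.float64)
    for d in directions:
        src, dst = _shift_slices(L.shape, d)
        # cont[v] = run continues from v to v + d
        cont = np.zeros(L.shape, bool)
        cont[src] = m[src] & m[dst] & (L[src] == L[dst])
        # start[v] = no same-level in-mask predecessor at v - d
        pred = np.zeros(L.shape, bool)
        pred[dst] = cont[src]
        start = m & ~pred
        pos = np.argwhere(start)
        run_lev = L[tuple(pos.T)]
        lengths = np.ones(len(pos), dtype=np.int64)
        active = np.arange(len(pos))
        step = np.asarray(d)
        cur = pos.copy()
        while active.size:
            ext = cont[tuple(cur[active].T)]
            active = active[ext]
            if active.size == 0:
                break
            lengths[active] += 1
            cur[active] += step
        np.add.at(R, (run_lev - 1, lengths - 1), 1.0)
    return R


def _run_zone_features(M: np.ndarray, n_voxel_positions: float, names) -> dict:
    """The 11 shared run-/zone-length emphasis and nonuniformity features."""
    n = float(M.sum())
    ng, lmax = M.shape
    i2 = np.arange(1, ng + 1, dtype=np.float64)[:, None] ** 2
    l2 = np.arange(1, lmax + 1, dtype=np.float64)[None, :] ** 2
    f = {
        names[0]: float((M / l2).sum() / n),          # short emphasis
        names[1]: float((M * l2).sum() / n),          # long emphasis
        names[2]: float((M / i2).sum() / n),          # low grey-level
        names[3]: float((M * i2).sum() / n),          # high grey-level
        names[4]: float((M / (i2 * l2)).sum() / n),   # short + low
        names[5]: float((M / l2 * i2).sum() / n),     # short + high
        names[6]: float((M * l2 / i2).sum() / n),     # long + low
        names[7]: float((M * l2 * i2).sum() / n),     # long + high
        names[8]: float((M.sum(axis=1) ** 2).sum() / n),  # grey-level nonuniformity
        names[9]: float((M.sum(axis=0) ** 2).sum() / n),  # length nonuniformity
        names[10]: float(n / n_voxel_positions),      # run/zone percentage
    }
    return f


_GLRLM_NAMES = (
    "glrlm_sre", "glrlm_lre", "glrlm_lgre", "glrlm_hgre",
    "glrlm_srlge", "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge",
    "glrlm_glnu", "glrlm_rlnu", "glrlm_rp",
)

_GLZLM_NAMES = (
    "glzlm_sze", "glzlm_lze", "glzlm_lgze", "glzlm_hgze",
    "glzlm_szlge", "glzlm_szhge", "glzlm_lzlge", "glzlm_lzhge",
    "glzlm_glnu", "glzlm_zlnu", "glzlm_zp",
)


def glrlm_features(
    level_grid: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions=DIRECTIONS_13,
) -> dict:
    """11 run-length features from the direction-summed GLRLM.

    RP normalises total runs by the total run-covered voxel positions
    (= #directions x #voxels), so a constant 1D segment of length L scanned
    in its own direction has RP = 1/L.
    """
    M = glrlm_matrix(level_grid, mask, n_levels, directions)
    lmax = M.shape[1]
    positions = float((M * np.arange(1, lmax + 1)[None, :]).sum())
    return _run_zone_features(M, positions, _GLRLM_NAMES)


# --- GLZLM ------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glzlm_matrix(level_grid: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts z[i, s]: 26-connected components of constant level."""
    L = np.asarray(level_grid)
    m = np.asarray(mask, bool)
    n_vox = int(m.sum())
    if n_vox == 0:
        raise ValidationError("empty mask")
    Z = np.zeros((n_levels, n_vox), dtype=np.float64)
    for lev in np.unique(L[m]):
        lab, nz = ndimage.label((L == lev) & m, structure=_STRUCT_26)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(Z, (int(lev) - 1, sizes - 1), 1.0)
    return Z


def glzlm_features(level_grid: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    """11 zone-length features; ZP = #zones / #voxels."""
    Z = glzlm_matrix(level_grid, mask, n_levels)
    n_vox = float(np.asarray(mask, bool).sum())
    return _run_zone_features(Z, n_vox, _GLZLM_NAMES)


# --- full panel -------------------------------------------------------------


@dataclass
class FeatureVector:
    """The 38 named texture features of one region plus extraction provenance."""

    features: dict
    provenance: dict

    def __getitem__(self, name: str) -> float:
        return self.features[name]

    def as_series(self):
        import pandas as pd

        return pd.Series(self.features)


def extract_all(
    pair: VolumePair,
    mask: BinaryMask,
    spec: DiscretizationSpec = DiscretizationSpec(),
) -> FeatureVector:
    """Compute all 38 features of the SUV field over one mask.

    Degenerate regions (too few voxels or no valid co-occurrence pairs)
    yield explicit NaN entries for the affected features, never silent
    zeros. Deterministic: the same input always gives the same vector.
    """
    pair.geometry.require_match(mask.geometry, "volume pair and feature mask")
    if mask.count < 2:
        raise ValidationError(f"mask has {mask.count} voxels; need >= 2 for texture analysis")
    values = pair.suv[mask.data]
    level_grid = discretize_grid(pair.suv, mask, spec)
    levels = level_grid[mask.data]
    ng = spec.n_levels

    feats: dict = {}
    feats.update(first_order_features(values, levels, ng))
    try:
        feats.update(glcm_features(glcm_matrix(level_grid, mask.data, ng)))
    except ValidationError:
        feats.update({k: float("nan") for k in
                      ("glcm_homogeneity", "glcm_energy", "glcm_contrast",
                       "glcm_correlation", "glcm_entropy", "glcm_dissimilarity")})
    feats.update(ngldm_features(level_grid, mask.data, ng))
    feats.update(glrlm_features(level_grid, mask.data, ng))
    feats.update(glzlm_features(level_grid, mask.data, ng))
    ordered = {name: feats[name] for name in FEATURE_NAMES}
    prov = dict(spec.provenance(), n_voxels=mask.count)
    return FeatureVector(ordered, prov)
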