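"""Texture features: closed-form cases, brute-force oracle equivalence,
conservation laws and symmetry invariances."""

import numpy as np
import pytest

from peritex import DiscretizationSpec, ValidationError
from peritex.io import BinaryMask, GridGeometry, VolumePair
from peritex.texture import (
    DIRECTIONS_13,
    FEATURE_NAMES,
    discretize,
    discretize_grid,
    extract_all,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glzlm_features,
    glzlm_matrix,
    ngldm_features,
)

from oracles import (
    brute_glcm,
    brute_glcm_features,
    brute_glrlm_features,
    brute_glzlm_features,
    brute_ngldm_features,
)
from conftest import random_roi


# --- discretisation ----------------------------------------------------------


@pytest.mark.parametrize(
    "values,spec,expected",
    [
        ([0.0, 10.0, 20.0], DiscretizationSpec(64, "absolute", (0, 20)), [1, 33, 64]),
        ([20.0], DiscretizationSpec(64, "absolute", (0, 20)), [64]),  # v == hi clamps to Ng
        ([25.0, -3.0], DiscretizationSpec(64, "absolute", (0, 20)), [64, 1]),
        ([2.0, 2.0, 2.0], DiscretizationSpec(8, "roi"), [1, 1, 1]),  # constant ROI
        ([0.0, 5.0, 10.0], DiscretizationSpec(4, "roi"), [1, 3, 4]),  # max -> Ng
    ],
)
def test_discretize_level_assignment(values, spec, expected):
    np.testing.assert_array_equal(discretize(np.array(values), spec), expected)


def test_discretize_rejects_bad_bounds():
    with pytest.raises(ValidationError):
        DiscretizationSpec(64, "absolute", (5.0, 5.0))


# --- first order --------------------------------------------------------------


def test_first_order_matches_direct_moments():
    rng = np.random.default_rng(3)
    v = rng.gamma(2.0, 1.0, 125)
    lev = discretize(v, DiscretizationSpec(16, "roi"))
    f = first_order_features(v, lev, 16)
    mean = v.sum() / v.size
    sd = np.sqrt(((v - mean) ** 2).sum() / v.size)
    m3 = ((v - mean) ** 3).sum() / v.size
    m4 = ((v - mean) ** 4).sum() / v.size
    assert f["suv_mean"] == pytest.approx(mean)
    assert f["suv_sd"] == pytest.approx(sd)
    assert f["suv_skewness"] == pytest.approx(m3 / sd**3)
    assert f["suv_kurtosis"] == pytest.approx(m4 / sd**4)
    assert f["suv_min"] == v.min() and f["suv_max"] == v.max()


def test_first_order_entropy_closed_forms():
    # two equal-mass bins -> exactly 1 bit
    v = np.array([1.0] * 8 + [9.0] * 8)
    lev = discretize(v, DiscretizationSpec(2, "roi"))
    assert first_order_features(v, lev, 2)["suv_hist_entropy"] == pytest.approx(1.0)
    # constant ROI -> entropy 0, moments undefined with a warning
    c = np.full(27, 2.5)
    with pytest.warns(RuntimeWarning):
        f = first_order_features(c, np.ones(27, int), 4)
    assert f["suv_hist_entropy"] == 0.0
    assert np.isnan(f["suv_skewness"]) and np.isnan(f["suv_kurtosis"])


# --- GLCM ---------------------------------------------------------------------


def test_glcm_constant_roi_degenerate_values():
    lev = np.ones((4, 4, 4), dtype=np.int64)
    mask = np.ones((4, 4, 4), bool)
    f = glcm_features(glcm_matrix(lev, mask, 4))
    assert f["glcm_entropy"] == pytest.approx(0.0)
    assert f["glcm_energy"] == pytest.approx(1.0)
    assert f["glcm_contrast"] == pytest.approx(0.0)
    assert f["glcm_homogeneity"] == pytest.approx(1.0)
    assert np.isnan(f["glcm_correlation"])  # zero marginal variance


def test_glcm_checkerboard_single_direction():
    # strict 2-level alternation along axis 0, scanned in that direction only:
    # p(1,2) = p(2,1) = 0.5 -> entropy 1 bit, contrast 1
    lev = np.indices((6, 1, 1)).sum(axis=0) % 2 + 1
    mask = np.ones((6, 1, 1), bool)
    f = glcm_features(glcm_matrix(lev, mask, 2, directions=[(1, 0, 0)]))
    assert f["glcm_entropy"] == pytest.approx(1.0)
    assert f["glcm_contrast"] == pytest.approx(1.0)
    assert f["glcm_dissimilarity"] == pytest.approx(1.0)


def test_glcm_isolated_voxels_error():
    lev = np.zeros((5, 5, 5), dtype=np.int64)
    mask = np.zeros((5, 5, 5), bool)
    mask[0, 0, 0] = mask[4, 4, 4] = True
    lev[mask] = 1
    with pytest.raises(ValidationError):
        glcm_matrix(lev, mask, 2)


# --- GLRLM --------------------------------------------------------------------


def test_glrlm_hand_enumerated_1d_examples():
    # row [A, A, B]: runs {(A,2),(B,1)}; SRE = (1/4 + 1)/2
    lev = np.array([1, 1, 2], dtype=np.int64).reshape(3, 1, 1)
    mask = np.ones((3, 1, 1), bool)
    f = glrlm_features(lev, mask, 2, directions=[(1, 0, 0)])
    assert f["glrlm_sre"] == pytest.approx(0.625)
    assert f["glrlm_rp"] == pytest.approx(2 / 3)
    # constant row of length L: LRE = L^2, RP = 1/L
    L = 7
    lev = np.ones((L, 1, 1), dtype=np.int64)
    f = glrlm_features(lev, np.ones((L, 1, 1), bool), 2, directions=[(1, 0, 0)])
    assert f["glrlm_lre"] == pytest.approx(L**2)
    assert f["glrlm_rp"] == pytest.approx(1 / L)


def test_glrlm_run_conservation_per_direction():
    rng = np.random.default_rng(8)
    lev, mask = random_roi(rng, (6, 6, 6), n_levels=3)
    n = int(mask.sum())
    for d in DIRECTIONS_13:
        M = glrlm_matrix(lev, mask, 3, directions=[d])
        lengths = np.arange(1, M.shape[1] + 1)
        assert (M * lengths).sum() == n  # every voxel in exactly one run


# --- GLZLM --------------------------------------------------------------------


def test_glzlm_closed_forms():
    # constant ROI of N voxels: one zone, ZP = 1/N, LZE = N^2
    n_side = 3
    lev = np.ones((n_side,) * 3, dtype=np.int64)
    mask = np.ones((n_side,) * 3, bool)
    f = glzlm_features(lev, mask, 2)
    N = n_side**3
    assert f["glzlm_zp"] == pytest.approx(1 / N)
    assert f["glzlm_lze"] == pytest.approx(N**2)
    assert f["glzlm_glnu"] == pytest.approx(1.0)


def test_glzlm_all_distinct_levels():
    lev = np.arange(1, 9, dtype=np.int64).reshape(2, 2, 2)
    mask = np.ones((2, 2, 2), bool)
    f = glzlm_features(lev, mask, 8)
    assert f["glzlm_sze"] == pytest.approx(1.0)
    assert f["glzlm_zp"] == pytest.approx(1.0)


def test_glzlm_zone_conservation():
    rng = np.random.default_rng(9)
    lev, mask = random_roi(rng, (6, 6, 6), n_levels=3)
    Z = glzlm_matrix(lev, mask, 3)
    sizes = np.arange(1, Z.shape[1] + 1)
    assert (Z * sizes).sum() == mask.sum()  # zones partition the mask


# --- NGLDM --------------------------------------------------------------------


def test_ngldm_constant_roi_degenerate():
    lev = np.ones((4, 4, 4), dtype=np.int64)
    f = ngldm_features(lev, np.ones((4, 4, 4), bool), 4)
    assert f["ngldm_contrast"] == 0.0
    assert f["ngldm_busyness"] == 0.0  # 0/0 convention
    assert np.isinf(f["ngldm_coarseness"])


# --- oracle equivalence (unit-scale; the full sweep runs in acceptance) ------


@pytest.mark.parametrize("seed", range(12))
def test_matrix_features_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 7, 3))
    lev, mask = random_roi(rng, shape, n_levels=int(rng.integers(2, 6)))
    ng = int(lev.max())
    got = {}
    got.update(glcm_features(glcm_matrix(lev, mask, ng)))
    got.update(glrlm_features(lev, mask, ng))
    got.update(glzlm_features(lev, mask, ng))
    got.update(ngldm_features(lev, mask, ng))
    want = {}
    want.update(brute_glcm_features(brute_glcm(lev, mask, ng)))
    want.update(brute_glrlm_features(lev, mask, ng))
    want.update(brute_glzlm_features(lev, mask, ng))
    want.update(brute_ngldm_features(lev, mask, ng))
    for k, v in want.items():
        if np.isnan(v):
            assert np.isnan(got[k]), k
        else:
            assert got[k] == pytest.approx(v, abs=1e-10), k


def test_features_invariant_to_axis_relabeling():
    """With the full 13-direction set on an isotropic grid, permuting the
    spatial axes must not change any matrix feature."""
    rng = np.random.default_rng(21)
    lev, mask = random_roi(rng, (5, 5, 5), n_levels=4)
    ng = 4

    def all_feats(L, m):
        out = {}
        out.update(glcm_features(glcm_matrix(L, m, ng)))
        out.update(glrlm_features(L, m, ng))
        out.update(glzlm_features(L, m, ng))
        out.update(ngldm_features(L, m, ng))
        return out

    base = all_feats(lev, mask)
    for perm in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
        other = all_feats(np.transpose(lev, perm), np.transpose(mask, perm))
        for k in base:
            if np.isnan(base[k]):
                assert np.isnan(other[k])
            else:
                assert other[k] == pytest.approx(base[k], rel=1e-12), (k, perm)


# --- full panel ---------------------------------------------------------------


def _toy_pair(rng, shape=(6, 6, 6)):
    geom = GridGeometry(shape, (2.0, 2.0, 2.0))
    suv = rng.gamma(2.0, 0.5, shape)
    hu = np.full(shape, -100.0)
    return VolumePair(suv, hu, geom), BinaryMask(rng.random(shape) < 0.7, geom)


def test_extract_all_is_deterministic_and_complete():
    rng = np.random.default_rng(5)
    pair, mask = _toy_pair(rng)
    a = extract_all(pair, mask)
    b = extract_all(pair, mask)
    assert tuple(a.features) == FEATURE_NAMES
    assert a.features == b.features
    assert a.provenance["disc_n_levels"] == 64
    finite = {k: v for k, v in a.features.items() if not np.isfinite(v)}
    assert not finite, f"unexpected non-finite features: {finite}"


def test_extract_all_glcm_entropy_probability_sums():
    rng = np.random.default_rng(6)
    pair, mask = _toy_pair(rng)
    spec = DiscretizationSpec(16, "roi")
    lev = discretize_grid(pair.suv, mask, spec)
    P = glcm_matrix(lev, mask.data, 16)
    assert P.sum() == pytest.approx(1.0)
    f = glcm_features(P)
    assert 0.0 <= f["glcm_entropy"] <= 2 * np.log2(16)
    assert 0.0 < f["glcm_energy"] <= 1.0
    assert 0.0 < f["glcm_homogeneity"] <= 1.0


def test_extract_all_rejects_degenerate_mask():
    rng = np.random.default_rng(7)
    pair, _ = _toy_pair(rng)
    tiny = np.zeros(pair.geometry.shape, bool)
    tiny[0, 0, 0] = True
    with pytest.raises(ValidationError):
        extract_all(pair, BinaryMask(tiny, pair.geometry))
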