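"""Independent brute-force oracles for texture matrices, distances and AUC.

Everything here is written as plain loops over voxels/pairs, deliberately
sharing no code with the package's vectorised implementations.
"""

from __future__ import annotations

from itertools import product

import numpy as np

ALL_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRS_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def brute_glcm(levels, mask, n_levels, directions=DIRS_13):
    """Symmetric pooled co-occurrence probabilities by pair enumeration."""
    shape = mask.shape
    counts = np.zeros((n_levels, n_levels))
    for v in product(*(range(s) for s in shape)):
        if not mask[v]:
            continue
        for d in directions:
            w = tuple(v[a] + d[a] for a in range(3))
            if _inside(shape, w) and mask[w]:
                i, j = levels[v] - 1, levels[w] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_glcm_features(p):
    ng = p.shape[0]
    hom = ene = con = ent = dis = 0.0
    mu = 0.0
    for i in range(ng):
        for j in range(ng):
            mu += (i + 1) * p[i, j]
    var = 0.0
    for i in range(ng):
        for j in range(ng):
            var += (i + 1 - mu) ** 2 * p[i, j]
    num = 0.0
    for i in range(ng):
        for j in range(ng):
            q = p[i, j]
            if q == 0:
                continue
            hom += q / (1 + abs(i - j))
            ene += q * q
            con += (i - j) ** 2 * q
            dis += abs(i - j) * q
            ent -= q * np.log2(q)
            num += (i + 1 - mu) * (j + 1 - mu) * q
    corr = num / var if var > 0 else float("nan")
    return {"glcm_homogeneity": hom, "glcm_energy": ene, "glcm_contrast": con,
            "glcm_correlation": corr, "glcm_entropy": ent, "glcm_dissimilarity": dis}


def brute_runs(levels, mask, direction):
    """All maximal same-level runs along one direction: list of (level, length)."""
    shape = mask.shape
    runs = []
    for v in product(*(range(s) for s in shape)):
        if not mask[v]:
            continue
        prev = tuple(v[a] - direction[a] for a in range(3))
        if _inside(shape, prev) and mask[prev] and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[a] + direction[a] for a in range(3))
            if _inside(shape, nxt) and mask[nxt] and levels[nxt] == levels[cur]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(levels[v]), length))
    return runs


def brute_glrlm_features(levels, mask, n_levels, directions=DIRS_13):
    runs = []
    for d in directions:
        runs.extend(brute_runs(levels, mask, d))
    nr = len(runs)
    positions = sum(l for _, l in runs)
    f = dict.fromkeys(
        ("glrlm_sre", "glrlm_lre", "glrlm_lgre", "glrlm_hgre", "glrlm_srlge",
         "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge"), 0.0)
    by_level: dict[int, int] = {}
    by_length: dict[int, int] = {}
    for i, l in runs:
        f["glrlm_sre"] += 1 / l**2
        f["glrlm_lre"] += l**2
        f["glrlm_lgre"] += 1 / i**2
        f["glrlm_hgre"] += i**2
        f["glrlm_srlge"] += 1 / (i**2 * l**2)
        f["glrlm_srhge"] += i**2 / l**2
        f["glrlm_lrlge"] += l**2 / i**2
        f["glrlm_lrhge"] += i**2 * l**2
        by_level[i] = by_level.get(i, 0) + 1
        by_length[l] = by_length.get(l, 0) + 1
    for k in f:
        f[k] /= nr
    f["glrlm_glnu"] = sum(c**2 for c in by_level.values()) / nr
    f["glrlm_rlnu"] = sum(c**2 for c in by_length.values()) / nr
    f["glrlm_rp"] = nr / positions
    return f


def brute_zones(levels, mask):
    """26-connected constant-level zones by flood fill: list of (level, size)."""
    shape = mask.shape
    seen = np.zeros(shape, bool)
    zones = []
    for v in product(*(range(s) for s in shape)):
        if not mask[v] or seen[v]:
            continue
        lev = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in ALL_26:
                w = tuple(cur[a] + d[a] for a in range(3))
                if _inside(shape, w) and mask[w] and not seen[w] and levels[w] == lev:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(lev), size))
    return zones


def brute_glzlm_features(levels, mask, n_levels):
    zones = brute_zones(levels, mask)
    nz = len(zones)
    n_vox = int(mask.sum())
    f = dict.fromkeys(
        ("glzlm_sze", "glzlm_lze", "glzlm_lgze", "glzlm_hgze", "glzlm_szlge",
         "glzlm_szhge", "glzlm_lzlge", "glzlm_lzhge"), 0.0)
    by_level: dict[int, int] = {}
    by_size: dict[int, int] = {}
    for i, s in zones:
        f["glzlm_sze"] += 1 / s**2
        f["glzlm_lze"] += s**2
        f["glzlm_lgze"] += 1 / i**2
        f["glzlm_hgze"] += i**2
        f["glzlm_szlge"] += 1 / (i**2 * s**2)
        f["glzlm_szhge"] += i**2 / s**2
        f["glzlm_lzlge"] += s**2 / i**2
        f["glzlm_lzhge"] += i**2 * s**2
        by_level[i] = by_level.get(i, 0) + 1
        by_size[s] = by_size.get(s, 0) + 1
    for k in f:
        f[k] /= nz
    f["glzlm_glnu"] = sum(c**2 for c in by_level.values()) / nz
    f["glzlm_zlnu"] = sum(c**2 for c in by_size.values()) / nz
    f["glzlm_zp"] = nz / n_vox
    return f


def brute_ngldm_features(levels, mask, n_levels):
    """Coarseness/contrast/busyness by per-voxel neighbourhood enumeration."""
    shape = mask.shape
    s_i = np.zeros(n_levels + 1)
    n_i = np.zeros(n_levels + 1)
    for v in product(*(range(s) for s in shape)):
        if not mask[v]:
            continue
        neigh = []
        for d in ALL_26:
            w = tuple(v[a] + d[a] for a in range(3))
            if _inside(shape, w) and mask[w]:
                neigh.append(levels[w])
        if not neigh:
            continue
        lev = int(levels[v])
        n_i[lev] += 1
        s_i[lev] += abs(lev - sum(neigh) / len(neigh))
    n_valid = n_i.sum()
    p_i = n_i / n_valid
    ps = sum(p_i[i] * s_i[i] for i in range(1, n_levels + 1))
    coarseness = 1 / ps if ps > 0 else float("inf")
    present = [i for i in range(1, n_levels + 1) if p_i[i] > 0]
    if len(present) > 1:
        acc = 0.0
        for i in range(1, n_levels + 1):
            for j in range(1, n_levels + 1):
                acc += p_i[i] * p_i[j] * (i - j) ** 2
        contrast = acc / (len(present) * (len(present) - 1)) * s_i.sum() / n_valid
        denom = sum(abs(i * p_i[i] - j * p_i[j]) for i in present for j in present)
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {"ngldm_coarseness": coarseness, "ngldm_contrast": contrast,
            "ngldm_busyness": busyness}


def brute_auc(scores, labels):
    """AUC by explicit enumeration of all (positive, negative) pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    acc = 0.0
    for p in pos:
        for q in neg:
            acc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return acc / (len(pos) * len(neg))


def brute_shell(tumor, spacing, distance_mm):
    """Margin shell by O(N^2) pairwise voxel-centre distances."""
    shape = tumor.shape
    tumor_idx = np.argwhere(tumor)
    out = np.zeros(shape, bool)
    sp = np.asarray(spacing, float)
    for v in product(*(range(s) for s in shape)):
        if tumor[v]:
            continue
        dmin = min(np.linalg.norm((np.asarray(v) - t) * sp) for t in tumor_idx)
        if dmin <= distance_mm + 1e-9:
            out[v] = True
    return out
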