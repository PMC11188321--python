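"""Grey-level texture matrices and their features: GLCM, GLRLM, GLSZM, NGTDM.

GLCM and GLRLM use the 13 unique 3-D directions at distance 1; features are
computed per direction and then averaged ("averaged" aggregation). GLSZM
zones and NGTDM neighbourhoods use 26-connectivity over the whole VOI and
need no direction averaging.

Degenerate conventions (documented and tested): GLCM correlation of a
constant VOI is 0; NGTDM coarseness is capped at 1e6; ratios with a zero
denominator are 0.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from .catalogue import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    feature_name,
)
from .discretize import DiscretizedVOI

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
]

COARSENESS_CAP = 1e6

#: the 13 unique direction vectors (one per +/- pair) at Chebyshev distance 1
DIRECTIONS_13 = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

_STRUCT26 = ndimage.generate_binary_structure(3, 3)


def _shift_pairs(levels: np.ndarray, mask: np.ndarray, d: tuple[int, int, int]):
    """Aligned (level, neighbour level) arrays for in-mask voxel pairs along d."""
    sl_a, sl_b = [], []
    for off, n in zip(d, levels.shape):
        if off == 0:
            sl_a.append(slice(None)); sl_b.append(slice(None))
        elif off > 0:
            sl_a.append(slice(0, n - off)); sl_b.append(slice(off, n))
        else:
            sl_a.append(slice(-off, n)); sl_b.append(slice(0, n + off))
    a, b = levels[tuple(sl_a)], levels[tuple(sl_b)]
    valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    return a[valid], b[valid]


# ---------------------------------------------------------------- GLCM

def glcm_matrix(voi: DiscretizedVOI, direction, distance: int = 1) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one direction."""
    ng = voi.n_bins
    d = tuple(int(c) * distance for c in direction)
    a, b = _shift_pairs(voi.levels, voi.mask, d)
    mat = np.zeros((ng, ng), dtype=np.float64)
    if len(a):
        # symmetric counting: each pair contributes to (a,b) and (b,a)
        np.add.at(mat, (a - 1, b - 1), 1.0)
        np.add.at(mat, (b - 1, a - 1), 1.0)
        mat /= mat.sum()
    return mat


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    total = p.sum()
    if total == 0:
        return {human: 0.0 for _, human in GLCM_FEATURES}
    pi = p.sum(axis=1)  # marginal (symmetric)

    mu = float((ii * p).sum())
    # difference and sum distributions
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())
    nzd, nzs, nzp = p_diff[p_diff > 0], p_sum[p_sum > 0], p[p > 0]

    mu_m = float((i * pi).sum())
    var_m = float(((i - mu_m) ** 2 * pi).sum())
    if var_m > 0:
        corr = float((((ii - mu_m) * (jj - mu_m) * p).sum()) / var_m)
    else:
        corr = 0.0

    off = np.abs(ii - jj)
    inv_var_mask = off > 0
    out = {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": float(((ii - mu) ** 2 * p).sum()),
        "joint_entropy_log2": float(-(nzp * np.log2(nzp)).sum()),
        "difference_average": da,
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "difference_entropy": float(-(nzd * np.log2(nzd)).sum()),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_entropy": float(-(nzs * np.log2(nzs)).sum()),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float((off**2 * p).sum()),
        "dissimilarity": float((off * p).sum()),
        "inverse_difference": float((p / (1.0 + off)).sum()),
        "normalised_inverse_difference": float((p / (1.0 + off / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + off**2)).sum()),
        "normalised_inverse_difference_moment": float((p / (1.0 + (off / ng) ** 2)).sum()),
        "inverse_variance": float((p[inv_var_mask] / off[inv_var_mask] ** 2).sum()),
        "correlation": corr,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu_m) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu_m) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu_m) ** 4 * p).sum()),
    }
    return out


def glcm_features(voi: DiscretizedVOI, distance: int = 1) -> dict[str, float]:
    """The 23 GLCM features, averaged over the 13 directions."""
    if voi.n_voxels < 2:
        raise ValueError("GLCM needs at least 2 in-mask voxels")
    acc: dict[str, float] = {}
    n_dir = 0
    for d in DIRECTIONS_13:
        mat = glcm_matrix(voi, d, distance)
        if mat.sum() == 0:
            continue  # no voxel pairs along this direction
        vals = _glcm_single(mat)
        n_dir += 1
        for k, v in vals.items():
            acc[k] = acc.get(k, 0.0) + v
    if n_dir == 0:
        raise ValueError("no voxel pairs in any direction")
    return {
        feature_name("glcm", code, human): acc[human] / n_dir
        for code, human in GLCM_FEATURES
    }


# ---------------------------------------------------------------- GLRLM

def glrlm_matrix(voi: DiscretizedVOI, direction) -> np.ndarray:
    """Run-length matrix (Ng x max_run) for one direction.

    A run is a maximal sequence of collinear in-mask voxels sharing a level.
    """
    levels, mask = voi.levels, voi.mask
    ng = voi.n_bins
    d = np.asarray(direction)
    coords = np.argwhere(mask)
    in_run = set(map(tuple, coords))
    runs: dict[tuple[int, int], int] = {}
    max_run = 1
    shape = levels.shape
    for c in coords:
        prev = c - d
        # run starts where the predecessor is absent or differs in level
        if (
            all(0 <= p < s for p, s in zip(prev, shape))
            and tuple(prev) in in_run
            and levels[tuple(prev)] == levels[tuple(c)]
        ):
            continue
        length = 1
        nxt = c + d
        lv = levels[tuple(c)]
        while (
            all(0 <= p < s for p, s in zip(nxt, shape))
            and tuple(nxt) in in_run
            and levels[tuple(nxt)] == lv
        ):
            length += 1
            nxt = nxt + d
        runs[(lv, length)] = runs.get((lv, length), 0) + 1
        max_run = max(max_run, length)
    mat = np.zeros((ng, max_run), dtype=np.float64)
    for (lv, length), n in runs.items():
        mat[lv - 1, length - 1] = n
    return mat


def _rlm_single(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    ns = r.sum()
    i = np.arange(1, r.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, r.shape[1] + 1)[None, :].astype(float)
    ri = r.sum(axis=1)
    rj = r.sum(axis=0)
    return {
        "short_runs_emphasis": float((r / j**2).sum() / ns),
        "long_runs_emphasis": float((r * j**2).sum() / ns),
        "low_grey_level_run_emphasis": float((r / i**2).sum() / ns),
        "high_grey_level_run_emphasis": float((r * i**2).sum() / ns),
        "short_run_low_grey_level_emphasis": float((r / (i**2 * j**2)).sum() / ns),
        "short_run_high_grey_level_emphasis": float((r * i**2 / j**2).sum() / ns),
        "long_run_low_grey_level_emphasis": float((r * j**2 / i**2).sum() / ns),
        "long_run_high_grey_level_emphasis": float((r * i**2 * j**2).sum() / ns),
        "grey_level_non_uniformity": float((ri**2).sum() / ns),
        "run_length_non_uniformity": float((rj**2).sum() / ns),
        "run_percentage": float(ns / n_voxels),
    }


def glrlm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """The 11 GLRLM features, averaged over the 13 directions."""
    if voi.n_voxels < 1:
        raise ValueError("empty VOI")
    acc: dict[str, float] = {}
    for d in DIRECTIONS_13:
        vals = _rlm_single(glrlm_matrix(voi, d), voi.n_voxels)
        for k, v in vals.items():
            acc[k] = acc.get(k, 0.0) + v
    return {
        feature_name("glrlm", code, human): acc[human] / len(DIRECTIONS_13)
        for code, human in GLRLM_FEATURES
    }


# ---------------------------------------------------------------- GLSZM

def glszm_matrix(voi: DiscretizedVOI) -> np.ndarray:
    """Size-zone matrix (Ng x max_zone); zones are 26-connected same-level
    components over the whole VOI (no direction dependence)."""
    ng = voi.n_bins
    zones: dict[tuple[int, int], int] = {}
    max_zone = 1
    for lv in np.unique(voi.in_mask_levels):
        labels, n = ndimage.label((voi.levels == lv) & voi.mask, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            zones[(int(lv), int(s))] = zones.get((int(lv), int(s)), 0) + 1
            max_zone = max(max_zone, int(s))
    mat = np.zeros((ng, max_zone), dtype=np.float64)
    for (lv, s), n in zones.items():
        mat[lv - 1, s - 1] = n
    return mat


def glszm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """The 16 GLSZM features."""
    s = glszm_matrix(voi)
    ns = s.sum()
    if ns == 0:
        raise ValueError("empty VOI")
    nv = voi.n_voxels
    i = np.arange(1, s.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, s.shape[1] + 1)[None, :].astype(float)
    si = s.sum(axis=1)
    sj = s.sum(axis=0)
    p = s / ns
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    nzp = p[p > 0]
    out = {
        "small_zone_emphasis": float((s / j**2).sum() / ns),
        "large_zone_emphasis": float((s * j**2).sum() / ns),
        "low_grey_level_zone_emphasis": float((s / i**2).sum() / ns),
        "high_grey_level_zone_emphasis": float((s * i**2).sum() / ns),
        "small_zone_low_grey_level_emphasis": float((s / (i**2 * j**2)).sum() / ns),
        "small_zone_high_grey_level_emphasis": float((s * i**2 / j**2).sum() / ns),
        "large_zone_low_grey_level_emphasis": float((s * j**2 / i**2).sum() / ns),
        "large_zone_high_grey_level_emphasis": float((s * i**2 * j**2).sum() / ns),
        "grey_level_non_uniformity": float((si**2).sum() / ns),
        "normalised_grey_level_non_uniformity": float((si**2).sum() / ns**2),
        "zone_size_non_uniformity": float((sj**2).sum() / ns),
        "normalised_zone_size_non_uniformity": float((sj**2).sum() / ns**2),
        "zone_percentage": float(ns / nv),
        "grey_level_variance": float(((i - mu_i) ** 2 * p).sum()),
        "zone_size_variance": float(((j - mu_j) ** 2 * p).sum()),
        "zone_size_entropy": float(-(nzp * np.log2(nzp)).sum()),
    }
    return {feature_name("glszm", code, human): out[human] for code, human in GLSZM_FEATURES}


# ---------------------------------------------------------------- NGTDM

def ngtdm_table(voi: DiscretizedVOI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): voxel counts and summed absolute differences
    from the mean of the 26-neighbourhood (in-mask neighbours only)."""
    ng = voi.n_bins
    m = voi.mask.astype(np.float64)
    lv = voi.levels.astype(np.float64) * m
    kernel = np.ones((3, 3, 3)); kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    n = np.zeros(ng)
    s = np.zeros(ng)
    coords = np.argwhere(voi.mask)
    for c in coords:
        t = tuple(c)
        i = voi.levels[t]
        n[i - 1] += 1
        cnt = nbr_cnt[t]
        if cnt > 0:
            s[i - 1] += abs(i - nbr_sum[t] / cnt)
    return n, s


def ngtdm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """The 5 NGTDM features with zero-denominator conventions."""
    n, s = ngtdm_table(voi)
    nv = n.sum()
    if nv == 0:
        raise ValueError("empty VOI")
    p = n / nv
    act = p > 0
    i_lv = np.arange(1, len(p) + 1, dtype=float)
    ngp = int(act.sum())

    dot_ps = float((p * s).sum())
    coarseness = min(1.0 / dot_ps, COARSENESS_CAP) if dot_ps > 0 else COARSENESS_CAP

    if ngp > 1:
        ii, jj = np.meshgrid(i_lv[act], i_lv[act], indexing="ij")
        pi, pj = np.meshgrid(p[act], p[act], indexing="ij")
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1)) * float(s.sum()) / nv
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = dot_ps / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (pi * s[act][:, None] + pj * s[act][None, :])
                            / (pi + pj)).sum()) / nv
        strength = (float(((pi + pj) * (ii - jj) ** 2).sum()) / s.sum()) if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    out = {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
    return {feature_name("ngtdm", code, human): out[human] for code, human in NGTDM_FEATURES}
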