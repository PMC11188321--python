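"""Independent brute-force oracles for the texture-feature families.

Everything here is written as plain Python loops over voxels, pairs, runs
and zones — no shared code with the package implementation — so agreement
is a real cross-check of both the matrix construction and the feature
formulas.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
NEIGH26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inside(c, shape):
    return all(0 <= x < s for x, s in zip(c, shape))


# ------------------------------------------------------------------ GLCM

def glcm_matrix_oracle(levels, mask, ng, direction):
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    mat = np.zeros((ng, ng))
    shape = levels.shape
    for c in np.argwhere(mask):
        nb = tuple(c + np.array(direction))
        if _inside(nb, shape) and mask[nb]:
            a, b = levels[tuple(c)], levels[nb]
            mat[a - 1, b - 1] += 1
            mat[b - 1, a - 1] += 1
    return mat / mat.sum() if mat.sum() else mat


def glcm_features_oracle(levels, mask, ng):
    """Direction-averaged features via explicit loops over matrix entries."""
    per_dir = []
    for d in DIRS:
        p = glcm_matrix_oracle(levels, mask, ng, d)
        if p.sum() == 0:
            continue
        per_dir.append(_glcm_feats_loops(p))
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


def _glcm_feats_loops(p):
    ng = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    pm = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu_m = sum((i + 1) * pm[i] for i in range(ng))
    var_m = sum((i + 1 - mu_m) ** 2 * pm[i] for i in range(ng))

    pd_ = [0.0] * ng
    ps = [0.0] * (2 * ng + 1)
    for i in range(ng):
        for j in range(ng):
            pd_[abs(i - j)] += p[i, j]
            ps[i + j + 2] += p[i, j]
    da = sum(k * pd_[k] for k in range(ng))
    sa = sum(k * ps[k] for k in range(len(ps)))

    f = {}
    f["joint_maximum"] = p.max()
    f["joint_average"] = mu
    f["joint_variance"] = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    f["joint_entropy_log2"] = -sum(
        p[i, j] * math.log2(p[i, j]) for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    f["difference_average"] = da
    f["difference_variance"] = sum((k - da) ** 2 * pd_[k] for k in range(ng))
    f["difference_entropy"] = -sum(q * math.log2(q) for q in pd_ if q > 0)
    f["sum_average"] = sa
    f["sum_variance"] = sum((k - sa) ** 2 * ps[k] for k in range(len(ps)))
    f["sum_entropy"] = -sum(q * math.log2(q) for q in ps if q > 0)
    f["angular_second_moment"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    f["dissimilarity"] = sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    f["inverse_difference"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["normalised_inverse_difference"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    f["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    f["normalised_inverse_difference_moment"] = sum(
        p[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    f["inverse_variance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["correlation"] = (
        sum((i + 1 - mu_m) * (j + 1 - mu_m) * p[i, j] for i in range(ng) for j in range(ng)) / var_m
        if var_m > 0 else 0.0
    )
    f["autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    for name, power in (("cluster_tendency", 2), ("cluster_shade", 3), ("cluster_prominence", 4)):
        f[name] = sum(
            (i + 1 + j + 1 - 2 * mu_m) ** power * p[i, j] for i in range(ng) for j in range(ng)
        )
    return f


# ------------------------------------------------------------------ GLRLM

def glrlm_runs_oracle(levels, mask, direction):
    """All maximal same-level runs along one direction, by line scanning."""
    shape = levels.shape
    d = np.asarray(direction)
    runs = []
    for c in np.argwhere(mask):
        prev = tuple(c - d)
        lv = levels[tuple(c)]
        if _inside(prev, shape) and mask[prev] and levels[prev] == lv:
            continue  # not a run start
        length = 1
        nxt = c + d
        while _inside(tuple(nxt), shape) and mask[tuple(nxt)] and levels[tuple(nxt)] == lv:
            length += 1
            nxt = nxt + d
        runs.append((int(lv), length))
    return runs


def glrlm_features_oracle(levels, mask):
    n_vox = int(mask.sum())
    per_dir = []
    for d in DIRS:
        runs = glrlm_runs_oracle(levels, mask, d)
        ns = len(runs)
        f = {
            "short_runs_emphasis": sum(1 / j**2 for _, j in runs) / ns,
            "long_runs_emphasis": sum(j**2 for _, j in runs) / ns,
            "low_grey_level_run_emphasis": sum(1 / i**2 for i, _ in runs) / ns,
            "high_grey_level_run_emphasis": sum(i**2 for i, _ in runs) / ns,
            "short_run_low_grey_level_emphasis": sum(1 / (i**2 * j**2) for i, j in runs) / ns,
            "short_run_high_grey_level_emphasis": sum(i**2 / j**2 for i, j in runs) / ns,
            "long_run_low_grey_level_emphasis": sum(j**2 / i**2 for i, j in runs) / ns,
            "long_run_high_grey_level_emphasis": sum(i**2 * j**2 for i, j in runs) / ns,
            "grey_level_non_uniformity": sum(
                sum(1 for i, _ in runs if i == lv) ** 2 for lv in set(i for i, _ in runs)
            ) / ns,
            "run_length_non_uniformity": sum(
                sum(1 for _, j in runs if j == ln) ** 2 for ln in set(j for _, j in runs)
            ) / ns,
            "run_percentage": ns / n_vox,
        }
        per_dir.append(f)
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


# ------------------------------------------------------------------ GLSZM

def glszm_zones_oracle(levels, mask):
    """Zones via explicit breadth-first flood fill, 26-connected."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        lv = levels[start]
        queue = [start]
        seen[start] = True
        size = 0
        while queue:
            c = queue.pop()
            size += 1
            for d in NEIGH26:
                nb = tuple(np.array(c) + d)
                if _inside(nb, shape) and mask[nb] and not seen[nb] and levels[nb] == lv:
                    seen[nb] = True
                    queue.append(nb)
        zones.append((int(lv), size))
    return zones


def glszm_features_oracle(levels, mask):
    zones = glszm_zones_oracle(levels, mask)
    ns = len(zones)
    nv = int(mask.sum())
    mu_i = sum(i for i, _ in zones) / ns
    mu_j = sum(j for _, j in zones) / ns
    from collections import Counter
    cnt = Counter(zones)
    probs = [n / ns for n in cnt.values()]
    return {
        "small_zone_emphasis": sum(1 / j**2 for _, j in zones) / ns,
        "large_zone_emphasis": sum(j**2 for _, j in zones) / ns,
        "low_grey_level_zone_emphasis": sum(1 / i**2 for i, _ in zones) / ns,
        "high_grey_level_zone_emphasis": sum(i**2 for i, _ in zones) / ns,
        "small_zone_low_grey_level_emphasis": sum(1 / (i**2 * j**2) for i, j in zones) / ns,
        "small_zone_high_grey_level_emphasis": sum(i**2 / j**2 for i, j in zones) / ns,
        "large_zone_low_grey_level_emphasis": sum(j**2 / i**2 for i, j in zones) / ns,
        "large_zone_high_grey_level_emphasis": sum(i**2 * j**2 for i, j in zones) / ns,
        "grey_level_non_uniformity": sum(
            sum(1 for i, _ in zones if i == lv) ** 2 for lv in set(i for i, _ in zones)
        ) / ns,
        "normalised_grey_level_non_uniformity": sum(
            sum(1 for i, _ in zones if i == lv) ** 2 for lv in set(i for i, _ in zones)
        ) / ns**2,
        "zone_size_non_uniformity": sum(
            sum(1 for _, j in zones if j == sz) ** 2 for sz in set(j for _, j in zones)
        ) / ns,
        "normalised_zone_size_non_uniformity": sum(
            sum(1 for _, j in zones if j == sz) ** 2 for sz in set(j for _, j in zones)
        ) / ns**2,
        "zone_percentage": ns / nv,
        "grey_level_variance": sum((i - mu_i) ** 2 for i, _ in zones) / ns,
        "zone_size_variance": sum((j - mu_j) ** 2 for _, j in zones) / ns,
        "zone_size_entropy": -sum(p * math.log2(p) for p in probs),
    }


# ------------------------------------------------------------------ NGTDM

def ngtdm_features_oracle(levels, mask, ng, coarseness_cap=1e6):
    shape = levels.shape
    n = [0.0] * ng
    s = [0.0] * ng
    for c in map(tuple, np.argwhere(mask)):
        i = int(levels[c])
        n[i - 1] += 1
        nb_vals = [
            levels[tuple(np.array(c) + d)]
            for d in NEIGH26
            if _inside(tuple(np.array(c) + d), shape) and mask[tuple(np.array(c) + d)]
        ]
        if nb_vals:
            s[i - 1] += abs(i - sum(nb_vals) / len(nb_vals))
    nv = sum(n)
    p = [x / nv for x in n]
    act = [i for i in range(ng) if p[i] > 0]
    ngp = len(act)
    dot = sum(p[i] * s[i] for i in act)
    coarseness = min(1 / dot, coarseness_cap) if dot > 0 else coarseness_cap
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in act for j in act)
            / (ngp * (ngp - 1)) * sum(s) / nv
        )
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in act for j in act if i != j)
        busyness = dot / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in act for j in act
        ) / nv
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in act for j in act) / sum(s)
            if sum(s) > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
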