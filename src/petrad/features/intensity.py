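"""First-order features: 20 continuous-intensity statistics on the raw SUVs
plus 23 intensity-histogram statistics on the discretized grey levels.

Conventions for degenerate VOIs (constant uptake): skewness and kurtosis are
defined as 0, the coefficient of variation as 0, and histogram gradients on a
single occupied level as 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volume import LesionMask, PETVolume
from .catalogue import FIRSTORDER_FEATURES, feature_name
from .discretize import DiscretizedVOI

__all__ = ["intensity_features", "global_intensity_peak"]

_PEAK_VOLUME_MM3 = 1000.0  # 1 cm^3 sphere


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """mean, population variance, skewness, excess kurtosis (0 conventions)."""
    mu = float(x.mean())
    var = float(x.var())
    if var == 0:
        return mu, 0.0, 0.0, 0.0
    z = (x - mu) / np.sqrt(var)
    return mu, var, float(np.mean(z**3)), float(np.mean(z**4) - 3.0)


def global_intensity_peak(volume: PETVolume, mask: LesionMask) -> float:
    """Mean SUV in the 1 cm^3 sphere whose centre (an in-mask voxel) maximizes it.

    The spherical neighbourhood may extend beyond the VOI; voxels outside the
    grid are handled by nearest-edge padding.
    """
    r = (3.0 * _PEAK_VOLUME_MM3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [int(np.floor(r / s)) for s in volume.spacing]
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, volume.spacing)],
                        indexing="ij")
    kernel = (grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2) <= r**2
    kernel = kernel.astype(np.float64)
    kernel /= kernel.sum()
    local_means = ndimage.convolve(volume.data, kernel, mode="nearest")
    return float(local_means[mask.data].max())


def _histogram_gradient(hist: np.ndarray) -> np.ndarray:
    """Centred-difference gradient of the level histogram (one-sided at ends)."""
    if len(hist) == 1:
        return np.zeros(1)
    grad = np.empty_like(hist, dtype=np.float64)
    grad[1:-1] = (hist[2:] - hist[:-2]) / 2.0
    grad[0] = hist[1] - hist[0]
    grad[-1] = hist[-1] - hist[-2]
    return grad


def intensity_features(
    volume: PETVolume, mask: LesionMask, discretized: DiscretizedVOI
) -> dict[str, float]:
    """The 43 first-order features on one VOI."""
    x = volume.data[mask.data].astype(np.float64)
    if x.size == 0:
        raise ValueError("empty mask")

    mu, var, skew, kurt = _moments(x)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    med = float(np.median(x))
    out = {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": med,
        "minimum": float(x.min()),
        "percentile_10": float(p10),
        "percentile_50": float(p50),
        "percentile_90": float(p90),
        "maximum": float(x.max()),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mu))),
        "robust_mean_absolute_deviation": float(np.mean(np.abs(robust - robust.mean()))),
        "median_absolute_deviation": float(np.mean(np.abs(x - med))),
        "coefficient_of_variation": float(np.sqrt(var) / mu) if mu != 0 else 0.0,
        "quartile_coefficient_of_dispersion": (
            float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0
        ),
        "energy": float(np.sum(x**2)),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "global_intensity_peak": global_intensity_peak(volume, mask),
    }

    # intensity-histogram statistics on the integer levels 1..Ng
    g = discretized.in_mask_levels.astype(np.float64)
    hmu, hvar, hskew, hkurt = _moments(g)
    hp10, hp25, hp50, hp75, hp90 = np.percentile(g, [10, 25, 50, 75, 90])
    hrobust = g[(g >= hp10) & (g <= hp90)]
    hmed = float(np.median(g))
    ng = discretized.n_bins
    hist = np.bincount(discretized.in_mask_levels, minlength=ng + 1)[1:].astype(np.float64)
    p = hist / hist.sum()
    nz = p[p > 0]
    occupied = np.flatnonzero(hist)
    grad = _histogram_gradient(hist[occupied[0]: occupied[-1] + 1]) if len(occupied) else np.zeros(1)
    grad_levels = np.arange(occupied[0], occupied[-1] + 1) + 1 if len(occupied) else np.array([1])

    out.update({
        "ih_mean": hmu,
        "ih_variance": hvar,
        "ih_skewness": hskew,
        "ih_kurtosis": hkurt,
        "ih_median": hmed,
        "ih_minimum": float(g.min()),
        "ih_percentile_10": float(hp10),
        "ih_percentile_90": float(hp90),
        "ih_maximum": float(g.max()),
        "ih_mode": float(np.argmax(hist) + 1),
        "ih_interquartile_range": float(hp75 - hp25),
        "ih_range": float(g.max() - g.min()),
        "ih_mean_absolute_deviation": float(np.mean(np.abs(g - hmu))),
        "ih_robust_mean_absolute_deviation": float(np.mean(np.abs(hrobust - hrobust.mean()))),
        "ih_median_absolute_deviation": float(np.mean(np.abs(g - hmed))),
        "ih_coefficient_of_variation": float(np.sqrt(hvar) / hmu) if hmu != 0 else 0.0,
        "ih_quartile_coefficient_of_dispersion": (
            float((hp75 - hp25) / (hp75 + hp25)) if (hp75 + hp25) != 0 else 0.0
        ),
        "ih_entropy_log2": float(-np.sum(nz * np.log2(nz))),
        "ih_uniformity": float(np.sum(p**2)),
        "max_histogram_gradient": float(grad.max()),
        "max_histogram_gradient_grey_level": float(grad_levels[int(np.argmax(grad))]),
        "min_histogram_gradient": float(grad.min()),
        "min_histogram_gradient_grey_level": float(grad_levels[int(np.argmin(grad))]),
    })

    return {
        feature_name("firstorder", code, human): float(out[human])
        for code, human in FIRSTORDER_FEATURES
    }
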