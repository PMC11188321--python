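"""Laplacian-of-Gaussian and single-level 3-D wavelet image filters.

These preprocessed images can optionally feed the feature extractor; the
default catalogue is computed on the original image only, so the transforms
are exercised mainly through their own invariants (linearity, perfect
reconstruction, sub-band energy).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pywt
from scipy import ndimage

from .volume import PETVolume

__all__ = ["FilteredVolume", "log_filter", "wavelet_decompose", "wavelet_reconstruct"]

#: Sub-band order: low/high along each axis, LLL first.
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
_PYWT_KEYS = {"L": "a", "H": "d"}


@dataclass
class FilteredVolume:
    """Filtered image with a provenance tag (filter + parameters)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str


def log_filter(volume: PETVolume, sigma_mm: float = 2.0) -> FilteredVolume:
    """Laplacian of Gaussian at physical scale ``sigma_mm``.

    The Gaussian sigma is converted to voxel units per axis so anisotropic
    grids are smoothed at a consistent physical scale; the operator is linear
    in the input.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    if sigma_mm < 0.5 * min(volume.spacing):
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below half the smallest voxel edge "
            f"({min(volume.spacing)} mm); response will be poorly resolved",
            stacklevel=2,
        )
    sigma_vox = [sigma_mm / s for s in volume.spacing]
    out = ndimage.gaussian_laplace(volume.data, sigma=sigma_vox, mode="nearest")
    # remove the DC residual of the truncated kernel so constants map to 0
    size = [2 * int(4.0 * sv + 0.5) + 3 for sv in sigma_vox]
    dc = ndimage.gaussian_laplace(np.ones(size), sigma=sigma_vox, mode="nearest")
    out -= dc[tuple(s // 2 for s in size)] * volume.data
    return FilteredVolume(
        data=out, spacing=volume.spacing, provenance=f"log(sigma={sigma_mm}mm)"
    )


def wavelet_decompose(
    volume: PETVolume, family: str = "coif1", level: int = 1
) -> dict[str, FilteredVolume]:
    """Separable single-level 3-D DWT; returns the 8 LLL..HHH sub-bands."""
    if level != 1:
        raise ValueError("only single-level decomposition is supported")
    if family not in pywt.wavelist(kind="discrete"):
        raise ValueError(
            f"unknown wavelet family {family!r}; supported discrete families: "
            f"{', '.join(pywt.wavelist(kind='discrete'))}"
        )
    wav = pywt.Wavelet(family)
    if min(volume.shape) < wav.dec_len:
        raise ValueError(
            f"volume shape {volume.shape} too small for filter length {wav.dec_len}"
        )
    coeffs = pywt.dwtn(volume.data, wav, mode="periodization")
    out = {}
    for band in WAVELET_BANDS:
        key = "".join(_PYWT_KEYS[c] for c in band)
        out[band] = FilteredVolume(
            data=coeffs[key],
            spacing=tuple(2 * s for s in volume.spacing),
            provenance=f"wavelet({family},band={band})",
        )
    return out


def wavelet_reconstruct(bands: dict[str, FilteredVolume], family: str = "coif1") -> np.ndarray:
    """Inverse of :func:`wavelet_decompose`."""
    coeffs = {
        "".join(_PYWT_KEYS[c] for c in band): fv.data for band, fv in bands.items()
    }
    return pywt.idwtn(coeffs, pywt.Wavelet(family), mode="periodization")
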