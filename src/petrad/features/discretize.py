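"""Fixed-bin-number grey-level discretization of a VOI.

Equal-width bins between the in-mask minimum and maximum; the minimum maps
to level 1 and the maximum to level Ng. Texture matrices operate on these
integer levels.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from ..volume import LesionMask, PETVolume

__all__ = ["DiscretizedVOI", "discretize", "DEFAULT_N_BINS"]

DEFAULT_N_BINS = 64


@dataclass
class DiscretizedVOI:
    """Integer grey levels 1..Ng over the mask; 0 marks out-of-mask voxels."""

    levels: np.ndarray  # int array, full grid, 0 outside mask
    mask: np.ndarray    # bool array
    n_bins: int
    bin_edges: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(volume: PETVolume, mask: LesionMask, n_bins: int = DEFAULT_N_BINS) -> DiscretizedVOI:
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    vals = volume.data[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant VOI: all voxels map to level 1; texture features degenerate",
                      stacklevel=2)
        levels[m] = 1
        edges = np.array([lo, hi])
    else:
        width = (hi - lo) / n_bins
        lv = np.floor((volume.data[m] - lo) / width).astype(np.int32) + 1
        np.clip(lv, 1, n_bins, out=lv)
        levels[m] = lv
        edges = lo + width * np.arange(n_bins + 1)
    return DiscretizedVOI(levels=levels, mask=m, n_bins=n_bins, bin_edges=edges,
                          spacing=volume.spacing)
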