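"""Lesion delineation by the 41%-of-SUVmax rule and metabolic metrics.

The volume of interest (VOI) for each lesion is the 26-connected component
of voxels whose SUV is at least 41% of the lesion's SUVmax, grown from a
user-supplied seed region (semi-automatic seeding). Lesions whose metabolic
tumor volume (MTV) falls below 10 cm^3 are excluded. Per-lesion metrics are
SUVmax, SUVmean, MTV (cm^3) and total lesion glycolysis TLG = SUVmean x MTV.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import ndimage

from .volume import LesionMask, PETVolume

__all__ = [
    "MetabolicMetrics",
    "segment_lesion",
    "filter_lesions",
    "metabolic_metrics",
    "patient_metrics",
    "merge_masks",
    "DEFAULT_THRESHOLD_FRACTION",
    "DEFAULT_MIN_MTV_CM3",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRACTION = 0.41
DEFAULT_MIN_MTV_CM3 = 10.0

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class MetabolicMetrics:
    """SUVmax / SUVmean (unitless), MTV (cm^3), TLG (cm^3 * SUV)."""

    suvmax: float
    suvmean: float
    mtv_cm3: float
    tlg: float

    def __post_init__(self) -> None:
        # tolerance: the mean of a uniform lesion can exceed the max by a
        # few ulps of floating-point summation error
        if self.suvmax < self.suvmean * (1.0 - 1e-12):
            raise ValueError("SUVmax must be >= SUVmean")
        if self.mtv_cm3 <= 0:
            raise ValueError("MTV must be positive")
        if abs(self.tlg - self.suvmean * self.mtv_cm3) > 1e-9 * max(1.0, abs(self.tlg)):
            raise ValueError("TLG must equal SUVmean * MTV")


def _seed_slices(volume: PETVolume, seed_region) -> tuple[slice, slice, slice]:
    """Normalize a seed voxel (i,j,k) or bounding box ((i0,i1),(j0,j1),(k0,k1))
    — stop indices exclusive — to slices, validated against the grid."""
    region = tuple(seed_region)
    if len(region) != 3:
        raise ValueError("seed_region must have three axis entries")
    slices = []
    for ax, r in enumerate(region):
        if np.isscalar(r):
            i0, i1 = int(r), int(r) + 1
        else:
            i0, i1 = int(r[0]), int(r[1])
        if not (0 <= i0 < i1 <= volume.shape[ax]):
            raise ValueError(
                f"seed region {r} on axis {ax} outside grid of size {volume.shape[ax]}"
            )
        slices.append(slice(i0, i1))
    return tuple(slices)


def segment_lesion(
    volume: PETVolume,
    seed_region,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    connectivity: int = 26,
    global_max: bool = False,
    lesion_id: int | str = 0,
) -> LesionMask:
    """Grow the VOI containing the seed at ``threshold_fraction`` x SUVmax.

    SUVmax is taken inside the seed region (semi-automatic mode) or over the
    whole volume when ``global_max`` is set. The mask is the ``connectivity``-
    connected component of supra-threshold voxels that contains the seed's
    hottest voxel.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    slices = _seed_slices(volume, seed_region)
    region = volume.data[slices]
    if region.size == 0:
        raise ValueError("seed region is empty")
    suvmax = float(volume.data.max() if global_max else region.max())
    threshold = threshold_fraction * suvmax
    above = volume.data >= threshold
    if not above.any():
        raise ValueError(f"no voxel reaches the threshold {threshold:.3g}")

    # hottest voxel inside the seed region anchors the component
    local_argmax = np.unravel_index(np.argmax(region), region.shape)
    anchor = tuple(s.start + a for s, a in zip(slices, local_argmax))
    if not above[anchor]:
        raise ValueError(
            f"seed voxel {anchor} (SUV {volume.data[anchor]:.3g}) is below the "
            f"threshold {threshold:.3g}; empty mask"
        )
    labels, _ = ndimage.label(above, structure=_STRUCTURES[connectivity])
    mask = labels == labels[anchor]
    return LesionMask(data=mask, spacing=volume.spacing, lesion_id=lesion_id, affine=volume.affine)


def filter_lesions(
    masks: list[LesionMask],
    volume: PETVolume,
    min_mtv_cm3: float = DEFAULT_MIN_MTV_CM3,
) -> list[LesionMask]:
    """Drop lesions with MTV strictly below ``min_mtv_cm3`` (order preserved)."""
    kept = []
    for m in masks:
        if m.shape != volume.shape:
            raise ValueError(f"mask {m.lesion_id} shape {m.shape} != volume {volume.shape}")
        if m.volume_cm3 >= min_mtv_cm3:
            kept.append(m)
        else:
            logger.info("lesion %s removed: MTV %.2f cm^3 < %.2f", m.lesion_id, m.volume_cm3, min_mtv_cm3)
    if not kept:
        logger.warning("all %d lesions removed by the %.1f cm^3 MTV filter", len(masks), min_mtv_cm3)
    return kept


def metabolic_metrics(volume: PETVolume, mask: LesionMask) -> MetabolicMetrics:
    """SUVmax / SUVmean / MTV / TLG over one mask."""
    if mask.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    vals = volume.data[mask.data]
    if vals.size == 0:
        raise ValueError("empty mask")
    suvmean = float(vals.mean())
    mtv = mask.n_voxels * volume.voxel_volume_cm3
    return MetabolicMetrics(
        suvmax=float(vals.max()), suvmean=suvmean, mtv_cm3=mtv, tlg=suvmean * mtv
    )


def merge_masks(masks: list[LesionMask], lesion_id: int | str = "merged") -> LesionMask:
    """Patient-level VOI: the union of all retained lesion masks."""
    if not masks:
        raise ValueError("no masks to merge")
    data = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        if m.shape != data.shape:
            raise ValueError("masks have inconsistent shapes")
        data |= m.data
    return LesionMask(data=data, spacing=masks[0].spacing, lesion_id=lesion_id, affine=masks[0].affine)


def patient_metrics(volume: PETVolume, masks: list[LesionMask]) -> MetabolicMetrics:
    """Patient-level metrics: SUVmax = max over lesions, MTV/TLG summed."""
    per_lesion = [metabolic_metrics(volume, m) for m in masks]
    if not per_lesion:
        raise ValueError("no lesions")
    mtv = sum(m.mtv_cm3 for m in per_lesion)
    tlg = sum(m.tlg for m in per_lesion)
    return MetabolicMetrics(
        suvmax=max(m.suvmax for m in per_lesion),
        suvmean=tlg / mtv,
        mtv_cm3=mtv,
        tlg=tlg,
    )
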