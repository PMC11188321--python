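"""Full-catalogue feature extraction for one VOI."""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import pandas as pd

from ..volume import LesionMask, PETVolume
from .catalogue import ALL_FEATURE_NAMES, N_FEATURES
from .discretize import DEFAULT_N_BINS, discretize
from .intensity import intensity_features
from .shape import shape_features
from .texture import glcm_features, glrlm_features, glszm_features, ngtdm_features

__all__ = ["ExtractionConfig", "extract_all", "features_to_frame"]


@dataclass
class ExtractionConfig:
    """Extraction settings echoed into run manifests for reproducibility."""

    n_bins: int = DEFAULT_N_BINS
    glcm_distance: int = 1
    #: compute the catalogue on wavelet/LoG filtered images as well
    filtered_images: bool = False
    wavelet_family: str = "coif1"
    log_sigma_mm: float = 2.0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "glcm_distance": self.glcm_distance,
            "filtered_images": self.filtered_images,
            "wavelet_family": self.wavelet_family,
            "log_sigma_mm": self.log_sigma_mm,
        }


def _extract_catalogue(volume: PETVolume, mask: LesionMask, config: ExtractionConfig) -> dict[str, float]:
    voi = discretize(volume, mask, n_bins=config.n_bins)
    out: dict[str, float] = {}
    out.update(shape_features(mask, volume.spacing, intensity=volume.data))
    out.update(intensity_features(volume, mask, voi))
    out.update(glcm_features(voi, distance=config.glcm_distance))
    out.update(glrlm_features(voi))
    out.update(ngtdm_features(voi))
    out.update(glszm_features(voi))
    return out


def extract_all(
    volume: PETVolume, mask: LesionMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract the 110-feature catalogue on the original image.

    With ``config.filtered_images`` set, the intensity/texture part of the
    catalogue is additionally computed on each wavelet sub-band and the LoG
    image, with the provenance tag prefixed to the feature name.

    Raises on any non-finite value (never silently emits NaN).
    """
    config = config or ExtractionConfig()
    out = _extract_catalogue(volume, mask, config)
    assert list(out) == ALL_FEATURE_NAMES and len(out) == N_FEATURES

    if config.filtered_images:
        from ..transforms import log_filter, wavelet_decompose

        filtered = {"log": log_filter(volume, config.log_sigma_mm)}
        filtered.update(
            {f"wavelet_{b}": fv for b, fv in
             wavelet_decompose(volume, config.wavelet_family).items()
             if b != "LLL"}
        )
        for tag, fv in filtered.items():
            if fv.data.shape != volume.shape:
                continue  # decimated sub-bands are not voxel-congruent with the mask
            fvol = PETVolume(data=fv.data - fv.data.min(), spacing=fv.spacing)
            fvoi = discretize(fvol, mask, n_bins=config.n_bins)
            for name, val in intensity_features(fvol, mask, fvoi).items():
                out[f"{tag}.{name}"] = val
            for name, val in glcm_features(fvoi, distance=config.glcm_distance).items():
                out[f"{tag}.{name}"] = val

    bad = [k for k, v in out.items() if not math.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature value(s): {', '.join(bad)}")
    return out


def features_to_frame(rows: list[dict[str, float]], index=None) -> pd.DataFrame:
    """Stack per-patient feature dicts into a DataFrame (one row per patient)."""
    return pd.DataFrame(rows, index=index)
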