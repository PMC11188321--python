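"""PET volume container and NIfTI round-trip IO.

A PET volume is a 3-D grid of standardized uptake values (SUV, dimensionless)
with a physical voxel spacing in millimetres. Whole-body lymphoma PET is
typically reconstructed on an isotropic 4 mm grid, which is the default
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["PETVolume", "LesionMask", "read_volume", "write_volume", "read_mask", "write_mask"]


@dataclass
class PETVolume:
    """3-D SUV-valued voxel grid with physical spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel SUVs; must be finite.
    spacing : tuple of float
        Voxel edge lengths in mm per axis, all > 0.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world transform. Defaults to a diagonal scaling by
        ``spacing`` (RAS, origin at the corner voxel).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            n_bad = int(np.sum(~np.isfinite(self.data)))
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


@dataclass
class LesionMask:
    """Boolean voxel mask congruent with its :class:`PETVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    lesion_id: int | str = 0
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        """Voxel-counting volume in cm^3 (the MTV of the mask)."""
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0


def _spacing_from_affine(img: nib.spatialimages.SpatialImage) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path) -> PETVolume:
    """Read a NIfTI PET volume; rejects files with non-finite voxels."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise IOError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    bad = ~np.isfinite(data)
    if bad.any():
        raise IOError(f"{path}: {int(bad.sum())} non-finite voxel(s) in volume")
    return PETVolume(data=data, spacing=_spacing_from_affine(img), affine=np.asarray(img.affine))


def write_volume(volume: PETVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine=volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path, lesion_id: int | str = 0) -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return LesionMask(
        data=data > 0.5,
        spacing=_spacing_from_affine(img),
        lesion_id=lesion_id,
        affine=np.asarray(img.affine),
    )


def write_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine=mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
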