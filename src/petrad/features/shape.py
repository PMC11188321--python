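"""Morphological (shape) features from an iso-surface mesh of the VOI.

Volume and surface area come from a marching-cubes triangulation of the
binary mask at physical spacing; the sphere-referenced ratios follow the
standard definitions (a sphere attains sphericity 1, the maximum over all
shapes of equal volume).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ..volume import LesionMask
from .catalogue import SHAPE_FEATURES, feature_name

__all__ = ["shape_features", "mesh_volume_area"]


def mesh_volume_area(mask: np.ndarray, spacing) -> tuple[float, float]:
    """Mesh volume (mm^3) and surface area (mm^2) of a binary mask.

    The indicator field is zero-padded (so the iso-surface closes) and
    anti-aliased with a one-voxel Gaussian before meshing: triangulating the
    raw binary field leaves stair-step facets whose area does not converge
    to the smooth surface (about +10% on a sphere), while the smoothed
    0.5-level set recovers sphere volume and area to a few tenths of a
    percent. Volume is the signed sum of tetrahedra spanned by the mesh
    triangles (divergence theorem). Single-voxel or otherwise
    mesh-degenerate masks fall back to voxel face-counting.
    """
    from scipy import ndimage

    padded = np.pad(mask.astype(np.float64), 2)
    padded = ndimage.gaussian_filter(padded, sigma=1.0)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        area = float(measure.mesh_surface_area(verts, faces))
        tri = verts[faces]
        vol = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
        if vol > 0 and area > 0:
            return vol, area
    except (ValueError, RuntimeError):
        pass
    # degenerate fallback: voxel-counting volume + exposed voxel-face area
    sp = tuple(spacing)
    face_areas = (sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1])
    m = mask.astype(np.int8)
    exposed = 0.0
    for ax, fa in enumerate(face_areas):
        diff = np.diff(np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)]), axis=ax)
        exposed += fa * float(np.abs(diff).sum())
    return float(mask.sum()) * float(np.prod(sp)), exposed


def _max_diameter(coords_mm: np.ndarray) -> float:
    """Largest pairwise distance between voxel centres (convex hull pruned)."""
    if len(coords_mm) == 1:
        return 0.0
    pts = coords_mm
    if len(pts) > 10:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # noqa: BLE001 - coplanar degenerate hulls
            pass
    return float(pdist(pts).max())


def shape_features(mask: LesionMask, spacing=None, intensity: np.ndarray | None = None) -> dict[str, float]:
    """The 12 shape features. ``intensity`` (full-grid SUV array) feeds the
    centre-of-mass shift and integrated intensity; without it the shift is 0
    and integrated intensity uses unit uptake."""
    sp = tuple(spacing) if spacing is not None else mask.spacing
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")

    vol_mesh, area = mesh_volume_area(m, sp)
    vol_vox = float(m.sum()) * float(np.prod(sp))

    sphericity = (36.0 * np.pi * vol_mesh**2) ** (1.0 / 3.0) / area
    out = {
        "volume": vol_mesh,
        "approximate_volume": vol_vox,
        "surface_area": area,
        "surface_to_volume_ratio": area / vol_mesh,
        "compactness_1": vol_mesh / (np.sqrt(np.pi) * area**1.5),
        "compactness_2": 36.0 * np.pi * vol_mesh**2 / area**3,
        "spherical_disproportion": 1.0 / sphericity,
        "sphericity": sphericity,
        "asphericity": (area**3 / (36.0 * np.pi * vol_mesh**2)) ** (1.0 / 3.0) - 1.0,
    }

    coords = np.argwhere(m).astype(np.float64)
    coords_mm = (coords + 0.5) * np.asarray(sp)
    com_geom = coords_mm.mean(axis=0)
    if intensity is not None:
        w = intensity[m].astype(np.float64)
        if w.sum() <= 0:
            raise ValueError("non-positive total intensity in mask")
        com_w = (coords_mm * w[:, None]).sum(axis=0) / w.sum()
        mean_suv = float(w.mean())
    else:
        com_w = com_geom
        mean_suv = 1.0
    out["centre_of_mass_shift"] = float(np.linalg.norm(com_geom - com_w))
    out["maximum_3d_diameter"] = _max_diameter(coords_mm)
    out["integrated_intensity"] = mean_suv * vol_mesh

    return {feature_name("shape", code, human): float(out[human]) for code, human in SHAPE_FEATURES}
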