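"""14 shape features of the binary mask: 11 three-dimensional + 3 two-dimensional.

3D features come from a marching-cubes mesh of the (zero-padded) mask and
from the principal-component decomposition of the physical foreground
coordinates.  The 3 2D features are the maximal in-plane diameters over all
slices perpendicular to each of the three grid axes.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    pts = np.unique(points, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 30:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # coplanar/collinear sets
            pass
    return float(pdist(pts).max())


def _mesh(mask: np.ndarray, spacing: np.ndarray, smooth_sigma: float = 0.8):
    """Marching-cubes mesh of the mask.

    The binary volume is lightly smoothed before meshing (antialiasing):
    on coarse grids the staircase surface of a hard 0/1 mask inflates the
    measured area and makes surface-based features needlessly sensitive to
    resampling.  Tiny masks whose smoothed peak falls below the iso level
    are meshed unsmoothed.
    """
    padded = np.pad(mask.astype(float), 2)
    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(padded, smooth_sigma)
        if smoothed.max() > 0.55:
            padded = smoothed
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = measure.mesh_surface_area(verts, faces)
    tri = verts[faces]
    volume = float(np.abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    return volume, float(area)


def shape_features(mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> Dict[str, float]:
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing_mm, dtype=float)
    voxel_volume = float(np.prod(spacing))
    coords_vox = np.argwhere(mask)
    coords = coords_vox * spacing

    mesh_volume, surface_area = _mesh(mask, spacing)
    mesh_volume = max(mesh_volume, 1e-12)
    sphericity = (np.pi ** (1.0 / 3.0)) * (6.0 * mesh_volume) ** (2.0 / 3.0) / surface_area

    if len(coords) > 1:
        cov = np.cov(coords, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
    else:
        eigvals = np.zeros(3)
    axes = 4.0 * np.sqrt(eigvals)
    if eigvals[0] > 0:
        elongation = float(np.sqrt(eigvals[1] / eigvals[0]))
        flatness = float(np.sqrt(eigvals[2] / eigvals[0]))
    else:
        elongation = flatness = 1.0

    # 2D: max in-plane diameter over slices along each axis
    diam2d = []
    for axis in range(3):
        best = 0.0
        inplane = [a for a in range(3) if a != axis]
        for idx in np.unique(coords_vox[:, axis]):
            pts = coords_vox[coords_vox[:, axis] == idx][:, inplane] * spacing[inplane]
            best = max(best, _max_pairwise(pts))
        diam2d.append(best)

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": float(mask.sum() * voxel_volume),
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_pairwise(coords),
        "MajorAxisLength": float(axes[0]),
        "MinorAxisLength": float(axes[1]),
        "LeastAxisLength": float(axes[2]),
        "Elongation": elongation,
        "Flatness": flatness,
        "Maximum2DDiameterSlice": diam2d[0],
        "Maximum2DDiameterColumn": diam2d[1],
        "Maximum2DDiameterRow": diam2d[2],
    }
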