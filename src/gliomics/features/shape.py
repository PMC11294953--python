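"""The 14 canonical 3D shape descriptors of an ROI.

Surface area and mesh volume come from a marching-cubes triangulation of the
(zero-padded) binary mask; axis lengths from the principal moments of the
physical voxel-coordinate covariance; maximum diameters from pairwise
distances between boundary-voxel centres.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist
from skimage import measure

SHAPE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    # divergence theorem over the closed triangulated surface
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(pdist(points).max())


def shape_features(roi_voxels: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> dict:
    mask = np.asarray(roi_voxels, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    spacing = np.asarray(spacing_mm, dtype=float)

    # crop to bounding box (shape features are translation invariant)
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if min(mask.shape) == 1:
        warnings.warn("ROI is a single voxel thick along some axis; mesh "
                      "features computed on the padded mask", stacklevel=2)

    n = int(mask.sum())
    voxel_volume = n * float(np.prod(spacing))

    # anti-aliased isosurface: a 1-voxel Gaussian turns the staircase
    # boundary into a smooth 0.5-level set (binary fallback for ROIs too
    # small to span the level)
    padded = np.pad(mask, 4).astype(np.float64)
    smoothed = ndimage.gaussian_filter(padded, 1.0)
    field = smoothed if smoothed.max() > 0.55 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=tuple(spacing))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    mesh_volume = _mesh_volume(verts, faces)

    sphericity = (36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / surface_area

    # physical coordinates of boundary voxels for the diameters
    eroded = ndimage.binary_erosion(mask)
    boundary = np.argwhere(mask & ~eroded) * spacing
    max3d = _max_pairwise(boundary)
    # per-plane maxima: fix one array axis, measure in the remaining plane
    plane_max = []
    for fixed_axis in (2, 1, 0):  # slice, column, row planes
        keep = [ax for ax in range(3) if ax != fixed_axis]
        best = 0.0
        coords = np.argwhere(mask & ~eroded)
        for v in np.unique(coords[:, fixed_axis]):
            pts = coords[coords[:, fixed_axis] == v][:, keep] * spacing[keep]
            best = max(best, _max_pairwise(pts))
        plane_max.append(best)
    max2d_slice, max2d_col, max2d_row = plane_max

    coords = np.argwhere(mask) * spacing
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    if eig[0] > 0:
        elongation = float(np.sqrt(eig[1] / eig[0]))
        flatness = float(np.sqrt(eig[2] / eig[0]))
    else:  # single voxel: dimensionless ratios default to 1
        elongation = 1.0
        flatness = 1.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_col,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
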