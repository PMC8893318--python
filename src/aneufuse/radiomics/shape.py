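"""3-D shape features of a binary mask: the standard 14-feature battery.

Mesh-based quantities (volume, surface area, sphericity, diameters) come
from a marching-cubes isosurface of the zero-padded mask at level 0.5.
The binary mask is anti-aliased with a 0.5-voxel Gaussian before meshing:
raw binary isosurfaces carry a staircase artifact that inflates surface
area by ~10% (a radius-10-voxel digital ball would score sphericity 0.91
instead of ~1), while the mild smoothing keeps enclosed volume within ~2%;
axis lengths, elongation and flatness from the inertia (covariance)
eigenvalues of the foreground voxel centres in physical coordinates.

Diameter plane convention for the three maximum 2-D diameters, in this
package's (x, y, z) axis order: "slice" drops z (x–y plane), "row" drops y
(x–z plane), "column" drops x (y–z plane).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes

from ..types import GeometryError, SegMask

SHAPE_NAMES = (
    "mesh_volume",
    "voxel_volume",
    "surface_area",
    "surface_volume_ratio",
    "sphericity",
    "maximum_3d_diameter",
    "maximum_2d_diameter_slice",
    "maximum_2d_diameter_row",
    "maximum_2d_diameter_column",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance; convex hull prunes the candidate set."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 50 and points.shape[1] >= 2:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:
            pass  # degenerate (flat) clouds: fall back to all points
    if len(pts) > 4000:  # safety net; hulls of real masks are far smaller
        pts = pts[:: len(pts) // 4000 + 1]
    return float(pdist(pts).max())


def shape3d_features(mask: SegMask) -> dict[str, float]:
    """The 14 shape features.  Raises :class:`GeometryError` for masks too
    small to carry a surface (fewer than 2 foreground voxels)."""
    m = mask.data
    n_fg = int(m.sum())
    if n_fg < 2:
        raise GeometryError(f"mask has {n_fg} foreground voxel(s); shape features undefined")
    spacing = np.asarray(mask.spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))

    padded = np.pad(m.astype(float), 1)
    smoothed = gaussian_filter(padded, sigma=0.5)  # anti-alias the staircase
    if smoothed.max() <= 0.5:  # very thin mask: smoothing sank the isosurface
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=tuple(spacing))
    verts = verts - spacing  # undo the 1-voxel pad offset
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = float(0.5 * np.linalg.norm(cross, axis=1).sum())
    mesh_vol = float(
        abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0
    )

    idx = np.argwhere(m)
    coords = idx * spacing  # physical voxel centres
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n_fg
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.maximum(evals, 0.0)
    major, minor, least = (4.0 * np.sqrt(evals)).tolist()
    elongation = float(np.sqrt(evals[1] / evals[0])) if evals[0] > 0 else 0.0
    flatness = float(np.sqrt(evals[2] / evals[0])) if evals[0] > 0 else 0.0

    sphericity = float((36.0 * np.pi * mesh_vol**2) ** (1.0 / 3.0) / area) if area > 0 else 0.0

    return {
        "mesh_volume": mesh_vol,
        "voxel_volume": n_fg * voxel_volume,
        "surface_area": area,
        "surface_volume_ratio": area / mesh_vol if mesh_vol > 0 else 0.0,
        "sphericity": sphericity,
        "maximum_3d_diameter": _max_pairwise(verts),
        "maximum_2d_diameter_slice": _max_pairwise(verts[:, [0, 1]]),
        "maximum_2d_diameter_row": _max_pairwise(verts[:, [0, 2]]),
        "maximum_2d_diameter_column": _max_pairwise(verts[:, [1, 2]]),
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": elongation,
        "flatness": flatness,
    }
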