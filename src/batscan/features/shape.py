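"""3D shape descriptors of a binary ROI: the standard 14-value set.

Surface quantities come from a marching-cubes mesh of the mask (computed
once on the original image geometry; shape features are not multiplied
across image types).  Axis lengths derive from the principal components
of the physical voxel-center coordinates (axis length = 4 * sqrt(eigval),
the full-axis length of the matching ellipsoid).  Degenerate flat or
single-voxel masks return defined values: zero axis lengths and ratios of
1 where the defining eigenvalue is zero.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist
from skimage import measure


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _max_pairwise(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    if len(coords) > 1200:  # thin out interior points; the diameter lives on the hull
        from scipy.spatial import ConvexHull

        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    return float(pdist(coords).max())


def shape_3d(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))
    n = int(mask.sum())

    verts, faces = _mesh(mask, spacing)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    mesh_volume = _mesh_volume(verts, faces)
    sphericity = (np.pi ** (1.0 / 3.0)) * ((6.0 * mesh_volume) ** (2.0 / 3.0)) / surface_area

    coords = np.argwhere(mask) * spacing
    diam3d = _max_pairwise(coords)

    # per-plane maximum in-plane diameters
    def plane_diam(axis: int) -> float:
        best = 0.0
        keep = [i for i in range(3) if i != axis]
        for v in np.unique(np.argwhere(mask)[:, axis]):
            pts = coords[np.argwhere(mask)[:, axis] == v][:, keep]
            if len(pts) >= 2:
                best = max(best, float(pdist(pts).max()))
        return best

    diam_slice = plane_diam(0)   # within one slice (row-column plane)
    diam_row = plane_diam(1)     # within one row (slice-column plane)
    diam_col = plane_diam(2)     # within one column (slice-row plane)

    centered = coords - coords.mean(axis=0)
    eigvals = np.sort(np.linalg.eigvalsh(np.cov(centered.T, bias=True)))[::-1] if n > 1 else np.zeros(3)
    eigvals = np.clip(eigvals, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(ev) for ev in eigvals)
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
    flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 1.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": diam3d,
        "Maximum2DDiameterSlice": diam_slice,
        "Maximum2DDiameterColumn": diam_col,
        "Maximum2DDiameterRow": diam_row,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elongation,
        "Flatness": flatness,
    }
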