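"""Shape statistics of a binary mask on its physical (mm) geometry.

Computed once per modality mask on the original, unfiltered grid: volume,
mesh surface area, sphericity, PCA axis lengths and maximum 3D diameter.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure


def shape_features(mask: np.ndarray, spacing_mm) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    voxel_volume = float(np.prod(spacing))
    n = int(mask.sum())
    feats: dict[str, float] = {}
    feats["VoxelVolume"] = n * voxel_volume

    # surface area from a marching-cubes mesh of the zero-padded mask
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    feats["SurfaceArea"] = area
    feats["SurfaceVolumeRatio"] = area / feats["VoxelVolume"]
    feats["Sphericity"] = float(
        (36.0 * np.pi * feats["VoxelVolume"] ** 2) ** (1.0 / 3.0) / area
    )

    # PCA of physical voxel-center coordinates
    coords = np.argwhere(mask) * spacing
    if n > 1:
        cov = np.cov(coords, rowvar=False, bias=False)
        eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    feats["MajorAxisLength"] = float(4.0 * np.sqrt(eig[0]))
    feats["MinorAxisLength"] = float(4.0 * np.sqrt(eig[1]))
    feats["LeastAxisLength"] = float(4.0 * np.sqrt(eig[2]))
    feats["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    feats["Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    # maximum pairwise distance between voxel centers (via convex hull)
    if n == 1:
        feats["Maximum3DDiameter"] = 0.0
    else:
        pts = coords
        if n > 10 and not np.allclose(pts.std(axis=0), 0):
            try:
                hull = ConvexHull(pts, qhull_options="QJ")
                pts = pts[hull.vertices]
            except Exception:
                pass
        feats["Maximum3DDiameter"] = float(pdist(pts).max())
    return feats
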