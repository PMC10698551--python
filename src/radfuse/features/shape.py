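"""Morphology (shape) features of a binary 3D mask.

Geometry is channel-independent: these are computed once per lesion from the
mask and repeated for every sequence.

Conventions:

* Surface area uses the voxel-face convention — the summed area of mask
  faces exposed to background. Sphericity therefore evaluates to
  ``(36*pi)**(1/3)/6`` for a cube, and ``Sphericity *
  SphericalDisproportion == 1`` identically.
* Axis lengths come from the eigenvalues of the covariance of voxel-center
  physical coordinates: ``length = 4*sqrt(lambda)``.
* ``Maximum2DDiameterSlice/Column/Row`` are the largest in-plane boundary
  diameters over slices perpendicular to the third/second/first axis.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

SHAPE_NAMES = (
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "SphericalDisproportion",
    "Compactness2",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _surface_area(mask: np.ndarray, spacing) -> float:
    sx, sy, sz = spacing
    face = (sy * sz, sx * sz, sx * sy)
    padded = np.pad(mask.astype(np.int8), 1)
    area = 0.0
    for axis, a in enumerate(face):
        d = np.diff(padded, axis=axis)
        area += a * np.count_nonzero(d)
    return float(area)


def _boundary_coords(mask: np.ndarray, spacing) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    coords = np.argwhere(boundary).astype(float) * np.asarray(spacing)
    return coords


def _max_pairwise(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    if len(coords) > 400:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except QhullError:
            pass
    return float(pdist(coords).max())


def _max_planar_diameter(mask: np.ndarray, spacing, axis: int) -> float:
    """Largest boundary diameter within any plane perpendicular to ``axis``."""
    other = [i for i in range(3) if i != axis]
    sp = [spacing[i] for i in other]
    best = 0.0
    for idx in range(mask.shape[axis]):
        sl = np.take(mask, idx, axis=axis)
        if not sl.any():
            continue
        er = ndimage.binary_erosion(sl)
        pts = np.argwhere(sl & ~er).astype(float) * np.asarray(sp)
        if len(pts) == 1:
            continue
        if len(pts) > 400:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except QhullError:
                pass
        best = max(best, float(pdist(pts).max()))
    return best


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """Return the 15 morphology features of a binary mask."""
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("mask must contain at least 2 voxels")
    spacing = tuple(float(s) for s in spacing)
    voxel_vol = spacing[0] * spacing[1] * spacing[2]
    volume = n * voxel_vol
    area = _surface_area(mask, spacing)
    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area

    coords = np.argwhere(mask).astype(float) * np.asarray(spacing)
    cov = np.cov(coords, rowvar=False)
    eigvals = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None))[::-1]
    major, minor, least = (4.0 * np.sqrt(eigvals[i]) for i in range(3))

    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": float(sphericity),
        "SphericalDisproportion": float(1.0 / sphericity),
        "Compactness2": float(sphericity**3),
        "Maximum3DDiameter": _max_pairwise(_boundary_coords(mask, spacing)),
        "Maximum2DDiameterSlice": _max_planar_diameter(mask, spacing, axis=2),
        "Maximum2DDiameterColumn": _max_planar_diameter(mask, spacing, axis=1),
        "Maximum2DDiameterRow": _max_planar_diameter(mask, spacing, axis=0),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eigvals[1] / eigvals[0]) if eigvals[0] > 0 else 0.0),
        "Flatness": float(np.sqrt(eigvals[2] / eigvals[0]) if eigvals[0] > 0 else 0.0),
    }
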