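"""Volume preprocessing: grid resampling, intensity normalization, discretization.

Every sequence volume passes through the same two steps before feature
extraction: resampling to a common voxel grid (1.096 x 1.096 x 1.2 mm by
default) and min-max normalization of intensities to 0-255. Texture features
additionally discretize the in-mask intensities to a fixed number of gray
levels (32 by default).

Conventions (documented because feature values depend on them):

* Resampling aligns half-voxel centers: output voxel ``i`` samples the input
  at physical position ``(i + 0.5) * s_out``, mapped to fractional input
  index ``pos / s_in - 0.5``. Output shape is ``ceil(extent / s_out)``.
* Intensities are interpolated linearly, masks by nearest neighbor.
* A zero-range (constant) volume normalizes to the midpoint 127.5.
* Discretization uses a fixed bin *count* over the in-mask range; the upper
  edge is assigned to the last bin, a constant region maps to bin 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters shared across all sequence channels."""

    target_spacing: tuple[float, float, float] = (1.096, 1.096, 1.2)
    intensity_range: tuple[float, float] = (0.0, 255.0)
    n_bins: int = 32

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError("intensity_range must satisfy min < max")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def resample(volume: np.ndarray, spacing, target_spacing, order: int = 1) -> np.ndarray:
    """Resample ``volume`` from ``spacing`` to ``target_spacing``.

    order=1 gives trilinear interpolation (intensities), order=0 nearest
    neighbor (masks).
    """
    volume = np.asarray(volume)
    spacing = np.asarray(spacing, dtype=float)
    target = np.asarray(target_spacing, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    extent = np.array(volume.shape) * spacing
    out_shape = np.maximum(np.ceil(extent / target - 1e-9).astype(int), 1)
    axes = [
        (np.arange(m) + 0.5) * t / s - 0.5
        for m, t, s in zip(out_shape, target, spacing)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        volume.astype(float), np.stack(grid), order=order, mode="nearest"
    )
    if order == 0:
        out = out.astype(volume.dtype)
    return out


def normalize_intensity(volume: np.ndarray, intensity_range=(0.0, 255.0)) -> np.ndarray:
    """Min-max map the whole volume onto ``intensity_range``.

    Constant volumes map to the midpoint of the range by convention.
    """
    volume = np.asarray(volume, dtype=float)
    lo, hi = intensity_range
    vmin, vmax = float(volume.min()), float(volume.max())
    if vmax - vmin == 0.0:
        return np.full_like(volume, (lo + hi) / 2.0)
    return lo + (volume - vmin) * (hi - lo) / (vmax - vmin)


def preprocess(volume: np.ndarray, mask: np.ndarray, config: PreprocessConfig | None = None,
               spacing=(1.0, 1.0, 1.0), lesion_id: str = "?") -> tuple[np.ndarray, np.ndarray]:
    """Resample volume+mask to the target grid and normalize intensities.

    Raises ``ValueError`` (naming the lesion) if the mask vanishes after
    resampling.
    """
    config = config or PreprocessConfig()
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must be congruent")
    vol = resample(volume, spacing, config.target_spacing, order=1)
    msk = resample(mask.astype(np.uint8), spacing, config.target_spacing, order=0)
    if msk.sum() == 0:
        raise ValueError(f"mask of lesion {lesion_id!r} vanished after resampling")
    vol = normalize_intensity(vol, config.intensity_range)
    return vol, msk.astype(bool)


def discretize(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed-bin-count discretization of in-mask intensities to levels 1..n_bins."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax - vmin == 0.0:
        return np.ones(values.shape, dtype=np.int64)
    levels = np.floor((values - vmin) / (vmax - vmin) * n_bins).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)
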