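"""First-order (intensity histogram) features.

Computed on the normalized in-mask intensities; ``Entropy`` and
``Uniformity`` use the fixed-bin-count discretized histogram. Percentiles
use linear interpolation between order statistics. Skewness and kurtosis are
population moments (kurtosis is *not* excess-corrected); both are 0 for a
constant region.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import discretize

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(values: np.ndarray, voxel_volume: float, n_bins: int = 32) -> dict[str, float]:
    """Return the 19 first-order features of a 1D array of in-mask intensities."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    n = x.size
    mean = x.mean()
    sd = x.std()  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    levels = discretize(x, n_bins)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n
    if sd > 0:
        skew = np.mean((x - mean) ** 3) / sd**3
        kurt = np.mean((x - mean) ** 4) / sd**4
    else:
        skew = 0.0
        kurt = 0.0
    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "StandardDeviation": float(sd),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(sd**2),
        "Uniformity": float(np.sum(p**2)),
    }
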