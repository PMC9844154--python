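"""First-order (intensity-histogram) features of a masked volume."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .preprocess import DiscretizedROI, ROIMask, VoxelVolume

__all__ = ["first_order_features", "FIRST_ORDER_FEATURE_NAMES"]

FIRST_ORDER_FEATURE_NAMES = [
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
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]


def first_order_features(
    volume: VoxelVolume, mask: ROIMask, roi: DiscretizedROI
) -> dict[str, float]:
    """The 18 standard intensity statistics.

    Entropy (bits) and uniformity are computed on the discretized gray
    levels; all other statistics on raw HU.  Skewness/kurtosis of a
    constant ROI are 0 (Fisher kurtosis convention: excess over normal,
    so a constant ROI reports 0, not -3).
    """
    x = volume.intensities[mask.mask].astype(np.float64)
    n = x.size
    voxel_volume = float(np.prod(volume.spacing_mm))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mean = float(x.mean())
    var = float(x.var())

    counts = np.bincount(roi.masked_levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    skew = float(stats.skew(x)) if var > 0 else 0.0
    kurt = float(stats.kurtosis(x, fisher=True)) if var > 0 else 0.0

    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": voxel_volume * float((x**2).sum()),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
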