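"""The 18 canonical first-order intensity statistics."""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(volume: np.ndarray, roi: np.ndarray,
                         disc: DiscretizedROI, spacing_mm=(1.0, 1.0, 1.0)) -> dict:
    """First-order features of the in-ROI intensity distribution.

    Entropy and Uniformity are computed on the discretized histogram; all
    moments are population moments. A constant ROI returns Skewness and
    Kurtosis of 0 by convention (kurtosis here is *not* excess kurtosis).
    """
    roi = np.asarray(roi, dtype=bool)
    x = np.asarray(volume, dtype=np.float64)[roi]
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    else:
        skew = 0.0
        kurt = 0.0

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    counts = np.bincount(disc.gray_levels[roi], minlength=disc.n_levels + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    energy = float((x ** 2).sum())
    voxel_volume = float(np.prod(spacing_mm))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
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
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": m2,
        "Uniformity": uniformity,
    }
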