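"""First-order (histogram) features: 18 values per ROI.

Entropy and Uniformity are computed on the discretized grey levels; all other
features use the raw ROI intensities. Moments are population (biased) moments
and Kurtosis is not excess-corrected.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize

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
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    values: np.ndarray, voxel_volume: float, bin_width: float
) -> dict[str, float]:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    dev = x - mean
    var = float((dev**2).mean())
    sd = np.sqrt(var)

    labels, n_bins = discretize(x, bin_width)
    p = np.bincount(labels, minlength=n_bins + 1)[1:] / n
    p_nz = p[p > 0]

    p10, p25, p50, p75, p90 = np.percentile(x, (10, 25, 50, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = float(np.abs(robust - robust.mean()).mean())
    else:
        rmad = 0.0

    if sd > 0:
        skew = float((dev**3).mean() / sd**3)
        kurt = float((dev**4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(dev).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
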