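"""First-order (intensity histogram) features, 18 in total.

Defined on the raw intensities inside the ROI; entropy and uniformity use
the fixed-bin-width discretized histogram. Moment-based statistics use the
population (biased) convention and kurtosis is uncorrected (a normal
distribution scores about 3). A constant region yields NaN for skewness
and kurtosis (flagged missing; filtered or imputed downstream).
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize

__all__ = ["FIRST_ORDER_NAMES", "first_order_features"]

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
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

_EPS = np.spacing(1.0)


def first_order_features(
    values: np.ndarray,
    bin_width: float,
    voxel_volume_mm3: float = 1.0,
    anchor: str = "roi_min",
) -> dict[str, float]:
    """The 18 first-order features of the intensities in a ROI.

    ``bin_width`` feeds the histogram-based Entropy and Uniformity;
    ``voxel_volume_mm3`` scales Energy into TotalEnergy.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    levels, _ = discretize(x, bin_width, anchor=anchor)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n

    robust = x[(x >= p10) & (x <= p90)]
    energy = float(np.sum(x**2))

    if m2 > 0:
        skewness = float(m3 / m2**1.5)
        kurtosis = float(m4 / m2**2)
    else:
        skewness = float("nan")
        kurtosis = float("nan")

    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume_mm3) * energy,
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else float("nan"),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
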