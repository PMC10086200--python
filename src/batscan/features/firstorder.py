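"""First-order (intensity histogram) features: the standard 18-value set.

Skewness and kurtosis use the population (biased) moment convention;
kurtosis is the raw fourth standardized moment (a normal distribution
gives 3).  Constant ROIs get skewness = kurtosis = 0 by the degenerate
rule.  Entropy and uniformity are computed on the same fixed-bin-width
discretization used by the texture matrices.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import discretize, effective_bin_width


def first_order(values: np.ndarray, mask: np.ndarray, voxel_volume: float = 1.0,
                bin_width: float = 25.0, max_levels: int | None = 64) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(values, dtype=float)[mask]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population convention
    p10, p25, p50, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]

    if var > 0:
        std = np.sqrt(var)
        skew = float(((x - mean) ** 3).mean() / std**3)
        kurt = float(((x - mean) ** 4).mean() / std**4)
    else:
        skew = kurt = 0.0

    bw = effective_bin_width(x, bin_width, max_levels)
    levels, _ = discretize(np.asarray(values, dtype=float), mask, bw)
    counts = np.bincount(levels[mask])[1:]
    p = counts[counts > 0] / n

    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
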