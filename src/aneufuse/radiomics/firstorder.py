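"""First-order (intensity histogram) features: the standard 18-feature battery.

All statistics are computed over the in-mask voxel intensities of the
preprocessed image; entropy and uniformity use the discretized gray levels.
Population moments throughout.  Degenerate (constant-ROI) rules: skewness
and kurtosis are defined as 0, entropy 0, uniformity 1.
"""

from __future__ import annotations

import numpy as np

from ..types import SegMask, ValidationError, VolumeImage
from .preprocess import DiscretizedROI

FIRSTORDER_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)


def first_order_features(
    volume: VolumeImage, mask: SegMask, roi: DiscretizedROI
) -> dict[str, float]:
    """The 18 first-order features.  Percentiles use linear interpolation
    (numpy default).  Kurtosis is the non-excess (Pearson) form, so a normal
    distribution scores 3."""
    mask.check_aligned(volume)
    x = volume.data[mask.data].astype(float)
    if x.size == 0:
        raise ValidationError("empty ROI")
    n = x.size
    mu = float(np.mean(x))
    var = float(np.var(x))  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    band = x[(x >= p10) & (x <= p90)]
    voxel_volume = float(np.prod(roi.spacing))

    levels = roi.levels[roi.mask]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))

    if var > 0:
        m = x - mu
        skew = float(np.mean(m**3) / var**1.5)
        kurt = float(np.mean(m**4) / var**2)
    else:
        skew, kurt = 0.0, 0.0

    return {
        "energy": float(np.sum(x**2)),
        "total_energy": voxel_volume * float(np.sum(x**2)),
        "entropy": entropy,
        "minimum": float(np.min(x)),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": float(np.max(x)),
        "mean": mu,
        "median": float(p50),
        "interquartile_range": float(p75 - p25),
        "range": float(np.max(x) - np.min(x)),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mu))),
        "robust_mean_absolute_deviation": float(np.mean(np.abs(band - np.mean(band)))),
        "root_mean_squared": float(np.sqrt(np.mean(x**2))),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": var,
        "uniformity": uniformity,
    }
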