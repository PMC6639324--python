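"""First-order features of the within-VOI intensity distribution.

Ten features summarize the masked intensity histogram: minimum, maximum, mean,
standard deviation, skewness, kurtosis, and the 1st, 5th, 95th and 99th
percentiles.  Estimator conventions (frozen here, in one place):

* standard deviation: sample estimator (n-1 denominator);
* skewness: Fisher g1, population (biased) definition m3 / m2^(3/2);
* kurtosis: excess kurtosis m4 / m2^2 - 3, population definition (normal -> 0);
* percentiles: linear interpolation between order statistics;
* zero-variance input: skewness = kurtosis = 0 by convention, so downstream
  feature tables never carry missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ParametricVolume, VOIMask

__all__ = ["HistogramFeatureSet", "HISTOGRAM_FEATURE_NAMES", "compute_histogram_features"]

HISTOGRAM_FEATURE_NAMES: tuple[str, ...] = (
    "minimum",
    "maximum",
    "mean",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "p01",
    "p05",
    "p95",
    "p99",
)


@dataclass(frozen=True)
class HistogramFeatureSet:
    minimum: float
    maximum: float
    mean: float
    standard_deviation: float
    skewness: float
    kurtosis: float
    p01: float
    p05: float
    p95: float
    p99: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in HISTOGRAM_FEATURE_NAMES}


def compute_histogram_features(volume: ParametricVolume, mask: VOIMask) -> HistogramFeatureSet:
    """Compute the 10 first-order features over the masked voxels only."""
    mask.check_companion(volume)
    x = volume.voxels[mask.voxels]
    return histogram_features_from_values(x)


def histogram_features_from_values(x: np.ndarray) -> HistogramFeatureSet:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty VOI: no voxels to summarize")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite voxels inside the VOI")
    p01, p05, p95, p99 = np.percentile(x, [1, 5, 95, 99])
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd > 0 and np.ptp(x) > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    else:
        skew = kurt = 0.0  # degenerate convention: constant sample
    return HistogramFeatureSet(
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        mean=float(np.mean(x)),
        standard_deviation=sd,
        skewness=skew,
        kurtosis=kurt,
        p01=float(p01),
        p05=float(p05),
        p95=float(p95),
        p99=float(p99),
    )
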