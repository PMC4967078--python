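"""First-order (histogram) density features over an ROI.

Eight features of the raw HU distribution inside a contour: mean, median,
standard deviation, variance, skewness, kurtosis, entropy and energy.
Moments use the population convention (divide by |Omega|); entropy (base-2
log) and energy are computed from a normalised histogram with one bin per
integer HU, with 0*log(0) := 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ROIMask, VolumeGrid

__all__ = ["HistogramFeatureSet", "histogram_features", "HISTOGRAM_FEATURES"]

HISTOGRAM_FEATURES = (
    "Mean",
    "Median",
    "Stddev",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Entropy",
    "Energy",
)


@dataclass(frozen=True)
class HistogramFeatureSet:
    mean: float
    median: float
    stddev: float
    variance: float
    skewness: float
    kurtosis: float
    entropy: float
    energy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Mean": self.mean,
            "Median": self.median,
            "Stddev": self.stddev,
            "Variance": self.variance,
            "Skewness": self.skewness,
            "Kurtosis": self.kurtosis,
            "Entropy": self.entropy,
            "Energy": self.energy,
        }


def histogram_features(
    volume: VolumeGrid,
    mask: ROIMask,
    kurtosis_denominator: str = "sigma4",
) -> HistogramFeatureSet:
    """Compute the eight histogram features over the masked voxels.

    Parameters
    ----------
    kurtosis_denominator : {"sigma4", "sigma3"}
        Normalisation of the fourth central moment.  ``sigma4`` is the
        standard (non-excess) kurtosis; ``sigma3`` preserves an alternative
        printed convention and is dimensionally inconsistent.

    Notes
    -----
    Median of an even-sized sample is the lower-middle order statistic.
    For a constant ROI (sigma = 0) skewness and kurtosis are reported as 0.
    """
    if kurtosis_denominator not in ("sigma4", "sigma3"):
        raise ValueError(f"unknown kurtosis_denominator {kurtosis_denominator!r}")
    mask.check_compatible(volume)
    if mask.count == 0:
        raise ValueError("empty mask")
    x = volume.values[mask.data].astype(float)
    n = x.size
    mu = float(x.mean())
    median = float(np.sort(x)[(n - 1) // 2])
    var = float(((x - mu) ** 2).mean())
    sigma = float(np.sqrt(var))
    if sigma > 0:
        skew = float(((x - mu) ** 3).mean() / sigma**3)
        m4 = float(((x - mu) ** 4).mean())
        kurt = m4 / (sigma**4 if kurtosis_denominator == "sigma4" else sigma**3)
    else:
        skew = 0.0
        kurt = 0.0
    # one bin per integer HU
    _, counts = np.unique(np.rint(x).astype(np.int64), return_counts=True)
    p = counts / n
    entropy = float(-(p * np.log2(p)).sum())
    energy = float((p**2).sum())
    return HistogramFeatureSet(mu, median, sigma, var, skew, kurt, entropy, energy)
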