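"""Respiratory-variability metrics over per-breath parameter series.

For each of the five per-breath parameter series (rate, Ti, Te, I/E ratio,
amplitude) computed from a fixed analysis window (default 300 s), seven
time-domain dispersion measures are taken:

* ``sd`` — sample standard deviation (n-1 denominator);
* ``cv`` — coefficient of variation, sd / mean;
* ``rmssd`` — root mean square of successive differences, the short-term
  fluctuation measure borrowed from heart-rate-variability analysis;
* ``tri_index`` — triangular index: series length divided by the modal
  histogram bin count (geometric dispersion; 1 for a constant series,
  approaching n for a flat histogram);
* ``sd1`` / ``sd2`` — Poincaré-plot dispersions perpendicular / parallel to
  the identity line of the lag-1 scatter (short- vs long-term variability);
* ``ellipse_area`` — pi * SD1 * SD2.

Poincaré dispersions use the population (n) variance so the identity
SD1 = RMSSD / sqrt(2) holds exactly on zero-mean-difference series; SD and
CV use the sample (n-1) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ProfileError, UndefinedMetricError

PARAMETERS = ("rate", "ti", "te", "ie_ratio", "amplitude")
METRICS = ("sd", "cv", "rmssd", "tri_index", "sd1", "sd2", "ellipse_area")

#: Default triangular-index bin widths per parameter.  The HRV convention of
#: 1/128 s does not transfer to breath series, so these are chosen at the
#: resolution scale of each parameter; amplitude (arbitrary units) uses a
#: data-driven IQR/10 width.
DEFAULT_BIN_WIDTHS = {
    "ti": 0.1,  # s
    "te": 0.1,  # s
    "rate": 1.0,  # breaths/min
    "ie_ratio": 0.05,
    "amplitude": None,  # -> IQR/10
}


def sd(series) -> float:
    """Sample standard deviation (n-1 denominator)."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise UndefinedMetricError("sd needs at least 2 values")
    return float(np.std(x, ddof=1))


def cv(series) -> float:
    """Coefficient of variation sd/mean (unitless); undefined at mean 0."""
    x = np.asarray(series, dtype=float)
    m = float(np.mean(x))
    if m == 0:
        raise UndefinedMetricError("cv undefined for zero-mean series")
    return sd(x) / m


def rmssd(series) -> float:
    """Root mean square of successive differences (mean over n-1 diffs)."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise UndefinedMetricError("rmssd needs at least 2 values")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d**2)))


def triangular_index(series, bin_width: float) -> float:
    """Series length / modal histogram count, bins of ``bin_width`` anchored at 0."""
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise UndefinedMetricError("triangular index needs at least 10 values")
    if np.ptp(x) == 0:
        return 1.0  # single occupied bin regardless of width
    if bin_width is None or bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    bins = np.floor(x / bin_width).astype(np.int64)
    bins -= bins.min()
    counts = np.bincount(bins)
    return float(len(x) / counts.max())


def poincare(series) -> tuple[float, float, float]:
    """Poincaré-plot (SD1, SD2, ellipse area) from lag-1 pairs.

    SD1 = population SD of (x_i - x_{i+1})/sqrt(2) (short-term variability),
    SD2 = population SD of (x_i + x_{i+1})/sqrt(2) (long-term variability),
    area = pi * SD1 * SD2.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise UndefinedMetricError("poincare needs at least 3 values")
    x1, x2 = x[:-1], x[1:]
    sd1 = float(np.std((x1 - x2) / math.sqrt(2), ddof=0))
    sd2 = float(np.std((x1 + x2) / math.sqrt(2), ddof=0))
    return sd1, sd2, math.pi * sd1 * sd2


@dataclass
class RVProfile:
    """All 35 `<parameter>_<metric>` values for one analysis window."""

    values: dict[str, float]
    n_breaths: int
    window_s: float

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, dtype=float)
        s["n_breaths"] = self.n_breaths
        return s


def amplitude_bin_width(series) -> float:
    iqr = float(np.subtract(*np.percentile(series, [75, 25])))
    return iqr / 10.0


def compute_rv_profile(
    bt: pd.DataFrame,
    bin_widths: dict | None = None,
    window_s: float = 300.0,
) -> RVProfile:
    """Compute the full 5-parameter x 7-metric RV profile of a breath table."""
    if len(bt) < 10:
        raise ProfileError(f"only {len(bt)} breaths; need at least 10 for a profile")
    widths = dict(DEFAULT_BIN_WIDTHS)
    if bin_widths:
        widths.update(bin_widths)
    values: dict[str, float] = {}
    for param in PARAMETERS:
        x = bt[param].to_numpy(dtype=float)
        values[f"{param}_sd"] = sd(x)
        values[f"{param}_cv"] = cv(x)
        values[f"{param}_rmssd"] = rmssd(x)
        w = widths.get(param)
        if w is None:
            w = amplitude_bin_width(x)
            if w <= 0:
                w = 1.0  # constant series handled inside triangular_index
        values[f"{param}_tri_index"] = triangular_index(x, w)
        sd1, sd2, area = poincare(x)
        values[f"{param}_sd1"] = sd1
        values[f"{param}_sd2"] = sd2
        values[f"{param}_ellipse_area"] = area
    return RVProfile(values=values, n_breaths=len(bt), window_s=window_s)


def feature_names() -> list[str]:
    """Canonical ordered list of the 35 profile feature names."""
    return [f"{p}_{m}" for p in PARAMETERS for m in METRICS]
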