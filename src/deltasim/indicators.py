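"""Headline indicators and their temporal aggregation.

Six region-level indicators: inundated area, mean/maximum soil salinity,
total rice production, poverty rate, income inequality (Gini) and
GDP per capita; plus the decadal-mean change against the 2005-2014
baseline that the sensitivity analysis is built on.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

BASELINE_DECADE = (2005, 2014)
ANALYSIS_DECADE_2050 = (2041, 2050)

INDICATOR_COLUMNS = (
    "inundated_area_km2",
    "mean_soil_salinity_dS_m",
    "max_soil_salinity_dS_m",
    "total_rice_t",
    "poverty_rate_pct",
    "gini",
    "gdp_per_capita",
)


def poverty_rate(poor_flags: np.ndarray, weights: np.ndarray) -> float:
    """Population-weighted poverty headcount, in percent.

    ``poor_flags`` may be boolean or fractional (e.g. a household's mean
    of monthly flags over a year); weights are population counts.
    """
    flags = np.asarray(poor_flags, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("total population weight must be positive")
    return float(100.0 * np.sum(flags * w) / total)


def gini(values: Sequence[float], weights: Optional[Sequence[float]] = None) -> float:
    """Weighted Gini index via the mean-absolute-difference formula.

    G = sum_ij w_i w_j |x_i - x_j| / (2 (sum w)^2 mean(x)).
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("values must be >= 0")
    if not np.any(x > 0):
        raise ValueError("at least one value must be positive")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    mean = np.sum(w * x) / wsum
    mad = np.sum(w[:, None] * w[None, :] * np.abs(x[:, None] - x[None, :]))
    return float(mad / (2.0 * wsum**2 * mean))


def gdp_per_capita(total_income: float, population: float) -> float:
    """Total income divided by total population."""
    if population <= 0:
        raise ValueError("population must be positive")
    return float(total_income) / float(population)


def decadal_mean(series: pd.Series, decade: tuple[int, int]) -> float:
    """Arithmetic mean of an annual series over an inclusive year window."""
    y0, y1 = decade
    window = series.loc[(series.index >= y0) & (series.index <= y1)]
    if len(window) != y1 - y0 + 1:
        raise ValueError(f"series does not fully cover {y0}-{y1}")
    return float(window.mean())


def baseline_change(
    run_value: float,
    baseline_value: float,
) -> tuple[float, Optional[float]]:
    """(absolute, percent) change of a decadal value against the baseline.

    Percent change is ``100 (value - baseline) / |baseline|``; when the
    baseline is zero the percent change is undefined and returned as
    ``None`` (absolute-only).
    """
    absolute = float(run_value - baseline_value)
    if baseline_value == 0:
        return absolute, None
    return absolute, float(100.0 * absolute / abs(baseline_value))


def decadal_baseline_change(
    series: pd.Series,
    decade: tuple[int, int] = ANALYSIS_DECADE_2050,
    baseline: tuple[int, int] = BASELINE_DECADE,
) -> tuple[float, Optional[float]]:
    """Change of the decadal mean vs the 2005-2014 baseline mean."""
    return baseline_change(decadal_mean(series, decade), decadal_mean(series, baseline))
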