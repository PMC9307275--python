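"""Monthly weather series -> annual standardized anomalies and annual variances.

A location's monthly temperature (or precipitation) series is z-scored over the
full weather window, decomposed additively into seasonal + trend + remainder
with STL (seasonal-trend decomposition by loess), and the remainder — the
weather *anomaly*, i.e. the deviation from the location's expected seasonal and
long-term pattern — is averaged per calendar year.  The annual within-year
variance of the *raw* monthly values is computed alongside as an alternative
weather driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import STL

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "AnomalySeries",
    "zscore_series",
    "stl_decompose",
    "annualize",
    "process_monthly",
    "annual_weather_table",
]

#: months per year; the seasonal period of every monthly series handled here
PERIOD = 12


def zscore_series(values):
    """Standardize a series to mean 0 and (sample) sd 1.

    Returns ``(z, mean, sd)`` so the transform can be inverted.

    Raises
    ------
    DegenerateInputError
        If the series is constant (sd == 0) or has fewer than 2 values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("need a 1-d series with at least 2 values")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("constant series cannot be z-scored")
    return (x - mean) / sd, mean, sd


def stl_decompose(series, seasonal_window=7, trend_window=1001,
                  inner_iter=2, outer_iter=0):
    """Additive STL decomposition of a monthly series (period 12).

    Parameters mirror the loess smoothing windows: ``seasonal_window`` is the
    seasonal smoother span (odd), ``trend_window`` the trend smoother span
    (odd; deliberately much longer than the series so the trend is very
    smooth).  Returns ``(seasonal, trend, remainder)`` summing exactly to the
    input.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 * PERIOD:
        raise InvalidArgumentError("STL needs at least 24 monthly values")
    if seasonal_window % 2 == 0 or trend_window % 2 == 0:
        raise InvalidArgumentError("loess windows must be odd")
    res = STL(x, period=PERIOD, seasonal=seasonal_window,
              trend=trend_window).fit(inner_iter=inner_iter, outer_iter=outer_iter)
    return res.seasonal, res.trend, res.resid


@dataclass
class AnomalySeries:
    """Decomposition products and annual summaries for one record/variable."""

    record_id: str
    variable: str
    years: np.ndarray          # calendar year per month
    months: np.ndarray         # 1..12 per month
    z: np.ndarray              # z-scored monthly input
    seasonal: np.ndarray
    trend: np.ndarray
    remainder: np.ndarray
    annual_years: np.ndarray   # complete calendar years only
    annual_anomaly: np.ndarray  # per-year mean of remainder
    annual_variance: np.ndarray  # per-year sample variance of raw values
    zscore_mean: float = 0.0
    zscore_sd: float = 1.0
    extras: dict = field(default_factory=dict)

    def annual_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "record_id": self.record_id,
            "variable": self.variable,
            "year": self.annual_years,
            "anomaly": self.annual_anomaly,
            "variance": self.annual_variance,
        })


def _complete_years(years, months):
    """Calendar years with all 12 months present, warning on partial years."""
    years = np.asarray(years)
    months = np.asarray(months)
    out = []
    for y in np.unique(years):
        n = (years == y).sum()
        if n == PERIOD:
            out.append(y)
        else:
            warnings.warn(f"dropping partial year {y} ({n}/12 months)",
                          stacklevel=3)
    return np.array(out)


def annualize(years, months, remainder, raw):
    """Annual anomaly (mean of monthly remainders) and annual variance
    (sample variance of raw monthly values) over complete years only."""
    years = np.asarray(years)
    months = np.asarray(months)
    remainder = np.asarray(remainder, dtype=float)
    raw = np.asarray(raw, dtype=float)
    keep = _complete_years(years, months)
    anom = np.empty(keep.size)
    var = np.empty(keep.size)
    for i, y in enumerate(keep):
        sel = years == y
        anom[i] = remainder[sel].mean()
        var[i] = raw[sel].var(ddof=1)
    return keep, anom, var


def process_monthly(record_id, variable, years, months, values,
                    seasonal_window=7, trend_window=1001) -> AnomalySeries:
    """Full z-score -> STL -> annualize chain for one monthly series."""
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)):
        raise InvalidArgumentError("monthly series contains non-finite values")
    z, mean, sd = zscore_series(values)
    seasonal, trend, remainder = stl_decompose(
        z, seasonal_window=seasonal_window, trend_window=trend_window)
    ay, anom, var = annualize(years, months, remainder, values)
    return AnomalySeries(
        record_id=record_id, variable=variable,
        years=np.asarray(years), months=np.asarray(months),
        z=z, seasonal=seasonal, trend=trend, remainder=remainder,
        annual_years=ay, annual_anomaly=anom, annual_variance=var,
        zscore_mean=mean, zscore_sd=sd,
    )


def annual_weather_table(weather_df: pd.DataFrame,
                         variables=("temp", "precip"),
                         seasonal_window=7, trend_window=1001) -> pd.DataFrame:
    """Annualize every (record_id, variable) monthly series of a long table.

    ``weather_df`` columns: record_id, year, month and one column per variable.
    Returns a long frame (record_id, variable, year, anomaly, variance).
    """
    frames = []
    for rid, grp in weather_df.groupby("record_id", sort=True):
        grp = grp.sort_values(["year", "month"])
        for var in variables:
            a = process_monthly(rid, var, grp["year"].to_numpy(),
                                grp["month"].to_numpy(), grp[var].to_numpy(),
                                seasonal_window=seasonal_window,
                                trend_window=trend_window)
            frames.append(a.annual_frame())
    if not frames:
        return pd.DataFrame(
            columns=["record_id", "variable", "year", "anomaly", "variance"])
    return pd.concat(frames, ignore_index=True)
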