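"""Anomaly construction: climatology removal and optional linear detrending.

An anomaly (denoted with a leading "d" in variable names, delta in the
science) is a monthly value minus the mean for that calendar month over a
baseline period, optionally with a single least-squares linear trend removed
from the deseasonalised series.  Missing months stay missing; nothing is
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import FluxGrid, GridContractError, RegionSeries

__all__ = [
    "AnomalyGrid",
    "monthly_climatology",
    "compute_anomalies",
    "seasonal_window_mean",
    "WINDOWS",
]

# Growing-season windows: spring = Apr-Jun, summer = Jul-Sep.
WINDOWS: dict[str, tuple[int, ...]] = {
    "AMJ": (4, 5, 6),
    "JAS": (7, 8, 9),
    "AprSep": (4, 5, 6, 7, 8, 9),
}


@dataclass
class AnomalyGrid(FluxGrid):
    """A FluxGrid of anomalies, retaining the climatology that produced it."""

    baseline: tuple[int, int] = (0, 0)
    detrended: bool = False
    climatology: np.ndarray | None = None  # (12, n_lat, n_lon)


def _month_numbers(time) -> np.ndarray:
    return np.array([m for _, m in time])


def monthly_climatology(
    grid: FluxGrid, baseline: tuple[int, int], min_years: int = 2
) -> np.ndarray:
    """Per-cell, per-calendar-month mean over baseline years.

    Returns a (12, n_lat, n_lon) array (index 0 = January).  A month is NaN
    wherever fewer than ``min_years`` baseline years contribute.
    """
    y0, y1 = baseline
    if y1 < y0:
        raise GridContractError("empty baseline period")
    years = np.array([y for y, _ in grid.time])
    months = _month_numbers(grid.time)
    in_base = (years >= y0) & (years <= y1)
    if not np.any(in_base):
        raise GridContractError("baseline period does not intersect the record")

    vals = grid.data_with_nan()
    clim = np.full((12,) + grid.values.shape[1:], np.nan)
    for m in range(1, 13):
        sel = in_base & (months == m)
        if not np.any(sel):
            continue
        sub = vals[sel]
        n = np.isfinite(sub).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(sub, axis=0)
        clim[m - 1] = np.where(n >= min_years, mean, np.nan)
    return clim


def _fractional_time(time) -> np.ndarray:
    """Fractional-year time axis (mid-month)."""
    return np.array([y + (m - 0.5) / 12.0 for y, m in time])


def compute_anomalies(
    grid: FluxGrid, baseline: tuple[int, int], detrend: bool = False
) -> AnomalyGrid:
    """Remove the baseline mean seasonal cycle; optionally detrend.

    The detrend step fits, per cell, a single ordinary-least-squares trend
    slope to the deseasonalised series against fractional-year time centred
    within each calendar month (the analogue of a trend regression with
    month fixed effects), plus the series mean, and subtracts the fit.
    Centring within months keeps the trend estimate free of seasonal-cycle
    leakage, so a pure seasonal cycle plus an exact linear ramp detrends to
    zero.  Missing entries remain missing; an all-missing cell stays
    all-missing.
    """
    clim = monthly_climatology(grid, baseline)
    vals = grid.data_with_nan()
    months = _month_numbers(grid.time)
    anoms = vals - clim[months - 1]

    if detrend:
        t = _fractional_time(grid.time)
        t = t - t.mean()
        nt = t.size
        flat = anoms.reshape(nt, -1)
        finite = np.isfinite(flat)
        a0 = np.where(finite, flat, 0.0)
        n = finite.sum(axis=0)
        # centre time within each calendar month (per cell, over its
        # non-missing entries), then fit one slope to all months jointly
        tc = np.zeros_like(flat)
        for m in range(1, 13):
            rows = months == m
            nm = finite[rows].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                tm = (t[rows, None] * finite[rows]).sum(axis=0) / nm
            tc[rows] = np.where(finite[rows], t[rows, None] - tm[None, :], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ym = a0.sum(axis=0) / n
            slope = (tc * a0).sum(axis=0) / (tc**2).sum(axis=0)
            slope = np.where((tc**2).sum(axis=0) > 0, slope, 0.0)
            fit = slope[None, :] * tc + ym[None, :]
        flat = np.where(finite, flat - fit, np.nan)
        anoms = flat.reshape(anoms.shape)

    return AnomalyGrid(
        variable_name=grid.variable_name,
        values=np.where(np.isfinite(anoms), anoms, np.nan),
        time=list(grid.time),
        lat_centers=grid.lat_centers,
        lon_centers=grid.lon_centers,
        units=grid.units,
        sign_convention=grid.sign_convention,
        baseline=(int(baseline[0]), int(baseline[1])),
        detrended=bool(detrend),
        climatology=clim,
    )


def seasonal_window_mean(obj, year: int, window: str):
    """Mean anomaly over a seasonal window of one year.

    ``obj`` may be a gridded field (returns a 2-D lat/lon array) or a
    :class:`RegionSeries` (returns a scalar).  All window months must be
    present and non-missing, else the result is NaN.
    """
    if window not in WINDOWS:
        raise GridContractError(f"unknown window {window!r}")
    months = WINDOWS[window]

    if isinstance(obj, RegionSeries):
        vals = []
        for m in months:
            if (year, m) not in obj.time:
                return float("nan")
            vals.append(obj.values[obj.time.index((year, m))])
        return float(np.mean(vals))

    idx = []
    for m in months:
        if (year, m) not in obj.time:
            shape = obj.values.shape[1:]
            return np.full(shape, np.nan)
        idx.append(obj.time.index((year, m)))
    sub = obj.data_with_nan()[idx]
    out = sub.mean(axis=0)  # NaN propagates when any month missing
    return out
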