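"""Attribution of flux anomalies to climate anomalies.

Two protocols:

* per-cell windowed Pearson correlations between yearly seasonal-window
  means of a flux anomaly field and a driver anomaly field, with two-sided
  t-test p-values (n - 2 degrees of freedom) and a P < 0.05 significance
  mask — including the lagged pairing (Apr-Sep driver vs Jul-Sep flux) that
  captures spring climate preconditioning summer fluxes;
* regional sensitivity regressions of Apr-Sep seasonal flux anomaly totals
  (PgC per season) on Apr-Sep regional driver anomaly means, giving slopes
  in PgC K-1 or PgC (m3 m-3)-1.

Years are treated as independent: no autocorrelation correction and no
multiple-testing correction across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anomaly import WINDOWS, seasonal_window_mean
from .grid import GridContractError, RegionSeries
from .metrics import SeasonalComponents

__all__ = [
    "DriverStats",
    "windowed_correlation",
    "sensitivity_regression",
    "component_driver_table",
]


@dataclass
class DriverStats:
    """Correlation/regression results for one flux-driver window pairing.

    Fields are scalars for regional statistics, 2-D lat/lon arrays for
    per-cell maps.  ``significant`` marks p < 0.05 (two-sided).
    """

    flux_window: str
    driver_window: str
    r: float | np.ndarray
    slope: float | np.ndarray
    intercept: float | np.ndarray
    r_squared: float | np.ndarray
    p_value: float | np.ndarray
    n_years: int | np.ndarray
    significant: bool | np.ndarray = False


def _yearly_window_stack(anoms, window: str, years: list[int]) -> np.ndarray:
    """(n_years, ...) stack of seasonal-window means."""
    return np.stack([np.asarray(seasonal_window_mean(anoms, y, window), float) for y in years])


def _pearson_with_p(x: np.ndarray, y: np.ndarray):
    """Vectorised Pearson r and two-sided t-test p along axis 0.

    NaNs are handled pairwise-complete per cell; cells with fewer than three
    common years come back NaN.
    """
    ok = np.isfinite(x) & np.isfinite(y)
    n = ok.sum(axis=0)
    x0 = np.where(ok, x, 0.0)
    y0 = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = x0.sum(axis=0) / n
        ym = y0.sum(axis=0) / n
        xc = np.where(ok, x - xm, 0.0)
        yc = np.where(ok, y - ym, 0.0)
        sxy = (xc * yc).sum(axis=0)
        sxx = (xc**2).sum(axis=0)
        syy = (yc**2).sum(axis=0)
        r = np.where(sxx * syy > 0, sxy / np.sqrt(sxx * syy), np.nan)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    df = np.maximum(n - 2, 1)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # exact fit: p -> 0
    p = np.where(np.isfinite(r) & ~np.isfinite(t), 0.0, p)
    bad = n < 3
    r = np.where(bad, np.nan, r)
    p = np.where(bad, np.nan, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm
    slope = np.where(bad, np.nan, slope)
    intercept = np.where(bad, np.nan, intercept)
    return r, p, slope, intercept, n


def windowed_correlation(
    flux,
    driver,
    flux_window: str,
    driver_window: str,
    alpha: float = 0.05,
) -> DriverStats:
    """Per-cell (or regional) correlation between yearly window means.

    For each cell, Pearson r between the driver's ``driver_window`` mean and
    the flux's ``flux_window`` mean across common years, with a two-sided
    t-test on n - 2 degrees of freedom and a significance mask at ``alpha``.
    """
    for w in (flux_window, driver_window):
        if w not in WINDOWS:
            raise GridContractError(f"unknown window {w!r}")
    if isinstance(flux, RegionSeries):
        f_years = sorted({y for y, _ in flux.time})
        d_years = sorted({y for y, _ in driver.time})
    else:
        f_years, d_years = flux.years, driver.years
    years = sorted(set(f_years) & set(d_years))
    if len(years) < 3:
        raise GridContractError("need at least three common years")

    f = _yearly_window_stack(flux, flux_window, years)
    d = _yearly_window_stack(driver, driver_window, years)
    r, p, slope, intercept, n = _pearson_with_p(d, f)
    if r.ndim == 0:
        r, p = float(r), float(p)
        slope, intercept, n = float(slope), float(intercept), int(n)
    return DriverStats(
        flux_window=flux_window,
        driver_window=driver_window,
        r=r,
        slope=slope,
        intercept=intercept,
        r_squared=np.square(r) if not np.isscalar(r) else r**2,
        p_value=p,
        n_years=n,
        significant=np.less(p, alpha, where=np.isfinite(p), out=np.zeros_like(np.asarray(p), dtype=bool))
        if not np.isscalar(p)
        else p < alpha,
    )


def sensitivity_regression(
    flux_region: RegionSeries,
    driver_region: RegionSeries,
    window: str = "AprSep",
    alpha: float = 0.05,
) -> DriverStats:
    """Regional sensitivity: OLS of seasonal flux totals on driver means.

    The response is the yearly ``window`` mean monthly flux anomaly scaled
    by the window length (a seasonal total in PgC); the regressor is the
    yearly window mean driver anomaly (area-weighted regional mean).  Slope
    units are therefore PgC per driver unit (e.g. PgC K-1).
    """
    years = sorted({y for y, _ in flux_region.time} & {y for y, _ in driver_region.time})
    n_months = len(WINDOWS[window])
    xs, ys = [], []
    for y in years:
        x = seasonal_window_mean(driver_region, y, window)
        fy = seasonal_window_mean(flux_region, y, window)
        if np.isfinite(x) and np.isfinite(fy):
            xs.append(x)
            ys.append(fy * n_months)
    if len(xs) < 3:
        raise GridContractError("need at least three common complete years")
    x = np.array(xs)
    y = np.array(ys)
    if np.allclose(x, x[0]):
        raise GridContractError("driver has zero variance over the common years")
    res = stats.linregress(x, y)
    return DriverStats(
        flux_window=window,
        driver_window=window,
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_years=len(xs),
        significant=bool(res.pvalue < alpha),
    )


# driver windows examined against the comp/amp components
_COMPONENT_DRIVER_WINDOWS = {
    "T": ("AMJ", "AprSep"),
    "M": ("AMJ", "JAS", "AprSep"),
    "P": ("AprSep",),
}


def component_driver_table(
    components: list[SeasonalComponents],
    drivers: dict[str, RegionSeries],
) -> pd.DataFrame:
    """Correlations of yearly comp/amp components with window driver anomalies.

    ``drivers`` maps a driver name (e.g. "T", "M", "P") to its regional
    anomaly series; each is correlated over the component years in the
    windows conventionally examined for it (all three windows if the name is
    not recognised).  Rows: component x driver x window, with Pearson r and
    its p-value; undefined correlations (zero variance) come back NaN.
    """
    if len(components) < 3:
        raise GridContractError("need at least three years of components")
    years = [c.year for c in components]
    rows = []
    for comp_name in ("comp", "amp"):
        cvals = np.array([float(getattr(c, comp_name)) for c in components])
        for dname, series in drivers.items():
            windows = _COMPONENT_DRIVER_WINDOWS.get(dname, ("AMJ", "JAS", "AprSep"))
            for w in windows:
                dvals = np.array([seasonal_window_mean(series, y, w) for y in years])
                ok = np.isfinite(cvals) & np.isfinite(dvals)
                if ok.sum() < 3 or np.ptp(cvals[ok]) == 0 or np.ptp(dvals[ok]) == 0:
                    r = p = np.nan
                else:
                    r, p = stats.pearsonr(cvals[ok], dvals[ok])
                rows.append(
                    {
                        "component": comp_name,
                        "driver": dname,
                        "window": w,
                        "r": r,
                        "p_value": p,
                        "n_years": int(ok.sum()),
                    }
                )
    return pd.DataFrame(rows)
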