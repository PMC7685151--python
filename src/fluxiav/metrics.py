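"""Seasonal compensation/amplification components and the RATIO statistic.

For each year the growing season is split into spring (Apr-Jun) and summer
(Jul-Sep).  With S_y and U_y the spring and summer mean anomalies:

    comp_y = U_y - S_y      (see-saw / seasonal compensation)
    amp_y  = U_y + S_y      (coherent whole-season amplification)

The multi-year RATIO = sum_y |comp_y| / sum_y |amp_y| measures which
behaviour dominates interannual variability: RATIO > 1 means compensation
dominates, < 1 amplification.  The statistic is scale-free but can blow up
when the amplification sum is tiny, so degenerate denominators are flagged
rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anomaly import AnomalyGrid, seasonal_window_mean
from .grid import GridContractError, RegionSeries

__all__ = [
    "SeasonalComponents",
    "RatioResult",
    "components_per_year",
    "ratio_metric",
    "ratio_map",
]


@dataclass
class SeasonalComponents:
    """Spring/summer mean anomalies and derived comp/amp for one year.

    Fields are scalars for a regional series, 2-D lat/lon arrays for grids.
    Exact identities: comp + amp = 2*summer, amp - comp = 2*spring.
    """

    year: int
    spring_mean: float | np.ndarray
    summer_mean: float | np.ndarray
    comp: float | np.ndarray
    amp: float | np.ndarray


@dataclass
class RatioResult:
    """The RATIO statistic with its constituent sums and year coverage."""

    ratio: float | np.ndarray
    sum_abs_comp: float | np.ndarray
    sum_abs_amp: float | np.ndarray
    years_used: list[int] = field(default_factory=list)
    degenerate: bool | np.ndarray = False


def components_per_year(anoms) -> list[SeasonalComponents]:
    """One SeasonalComponents per year with a complete Apr-Sep window.

    Accepts an anomaly grid (per-cell arrays) or a RegionSeries (scalars).
    Years with any missing Apr-Sep month are skipped (scalar case) or carry
    NaN in the affected cells (gridded case).
    """
    if isinstance(anoms, RegionSeries):
        years = sorted({y for y, _ in anoms.time})
    else:
        years = anoms.years
    out = []
    for y in years:
        s = seasonal_window_mean(anoms, y, "AMJ")
        u = seasonal_window_mean(anoms, y, "JAS")
        if np.isscalar(s) or isinstance(s, float):
            if not (np.isfinite(s) and np.isfinite(u)):
                continue
        elif not np.any(np.isfinite(s) & np.isfinite(u)):
            continue
        out.append(
            SeasonalComponents(
                year=y, spring_mean=s, summer_mean=u, comp=u - s, amp=u + s
            )
        )
    return out


def ratio_metric(components: list[SeasonalComponents]) -> RatioResult:
    """RATIO = sum_y |comp_y| / sum_y |amp_y| over the given years.

    A zero amplification sum is flagged ``degenerate`` and reported as +inf
    (the statistic is unbounded when amplification vanishes), keeping both
    sums available for inspection.
    """
    if len(components) < 2:
        raise GridContractError("ratio_metric needs at least two complete years")
    comp = np.stack([np.asarray(c.comp, dtype=float) for c in components])
    amp = np.stack([np.asarray(c.amp, dtype=float) for c in components])
    # a year enters both sums or neither (comp/amp are finite together)
    ok = np.isfinite(comp) & np.isfinite(amp)
    n_ok = ok.sum(axis=0)
    sc = np.where(ok, np.abs(comp), 0.0).sum(axis=0)
    sa = np.where(ok, np.abs(amp), 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(sa > 0, sc / sa, np.inf)
    ratio = np.where(n_ok >= 2, ratio, np.nan)
    sc = np.where(n_ok >= 2, sc, np.nan)
    sa = np.where(n_ok >= 2, sa, np.nan)
    degenerate = (sa == 0) & (n_ok >= 2)
    if ratio.ndim == 0:
        ratio, sc, sa, degenerate = float(ratio), float(sc), float(sa), bool(degenerate)
    return RatioResult(
        ratio=ratio,
        sum_abs_comp=sc,
        sum_abs_amp=sa,
        years_used=[c.year for c in components],
        degenerate=degenerate,
    )


def ratio_map(
    anoms: AnomalyGrid,
    temperature=None,
    soil_moisture=None,
) -> tuple[RatioResult, pd.DataFrame]:
    """Per-cell RATIO over the anomaly record, plus a cell table.

    The table carries one row per grid cell (lat, lon, ratio, the two sums,
    the number of complete years) and, when driver grids are supplied, the
    mean Apr-Sep soil temperature and moisture for scatter analysis of
    RATIO against climate.
    """
    comps = components_per_year(anoms)
    result = ratio_metric(comps)

    stack_c = np.stack([np.asarray(c.comp, float) for c in comps])
    n_years = np.isfinite(stack_c).sum(axis=0)

    lat2, lon2 = np.meshgrid(anoms.lat_centers, anoms.lon_centers, indexing="ij")
    table = pd.DataFrame(
        {
            "lat": lat2.ravel(),
            "lon": lon2.ravel(),
            "ratio": np.asarray(result.ratio).ravel(),
            "sum_abs_comp": np.asarray(result.sum_abs_comp).ravel(),
            "sum_abs_amp": np.asarray(result.sum_abs_amp).ravel(),
            "n_years": n_years.ravel(),
            "degenerate": np.asarray(result.degenerate).ravel(),
        }
    )
    for name, drv in (("mean_T_AprSep", temperature), ("mean_M_AprSep", soil_moisture)):
        if drv is None:
            continue
        months = [i for i, (_, m) in enumerate(drv.time) if 4 <= m <= 9]
        with np.errstate(invalid="ignore"):
            table[name] = np.nanmean(drv.data_with_nan()[months], axis=0).ravel()
    return result, table
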