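"""Gridded monthly fields: data model, NetCDF I/O, regridding, regional aggregation.

The common currency of the package is :class:`FluxGrid`, a monthly
(time, lat, lon) field on a regular latitude-longitude grid with an explicit
missing-value mask.  Fluxes are intensive (gC m-2 month-1); drivers carry
their native units (K, m3 m-3, mm month-1).  Regional aggregation converts
flux densities to regional totals in PgC month-1.

Longitudes are normalised to [-180, 180) and latitudes stored ascending, so
every downstream stage can assume one coordinate convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "EARTH_RADIUS_M",
    "GC_TO_PGC",
    "FluxGrid",
    "RegionMask",
    "RegionSeries",
    "month_range",
    "read_gridded",
    "write_gridded",
    "cell_areas",
    "area_weighted_regrid",
    "aggregate_region",
    "default_masks",
]

EARTH_RADIUS_M = 6_371_000.0
GC_TO_PGC = 1e-15

# Net ecosystem exchange sign convention used throughout: positive NEE is a
# flux from the land to the atmosphere (a carbon source).
NEE_SIGN_CONVENTION = "positive = flux from land to atmosphere"


class GridFormatError(ValueError):
    """A file or variable does not match the expected gridded-monthly layout."""


class GridContractError(ValueError):
    """Inputs violate a documented precondition."""


def month_range(start: tuple[int, int], n: int) -> list[tuple[int, int]]:
    """``n`` consecutive (year, month) labels starting at ``start``."""
    y, m = start
    out = []
    for _ in range(n):
        out.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def _check_consecutive(time: list[tuple[int, int]]) -> None:
    for (y0, m0), (y1, m1) in zip(time[:-1], time[1:]):
        nxt = (y0, m0 + 1) if m0 < 12 else (y0 + 1, 1)
        if (y1, m1) != nxt:
            raise GridContractError(
                f"time labels must be consecutive calendar months; "
                f"gap between {(y0, m0)} and {(y1, m1)}"
            )


def _uniform_spacing(coords: np.ndarray, name: str) -> float:
    d = np.diff(coords)
    if coords.size < 2:
        raise GridContractError(f"need at least two {name} values")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise GridContractError(f"{name} spacing is not uniform")
    if d[0] <= 0:
        raise GridContractError(f"{name} must be strictly ascending")
    return float(d[0])


@dataclass
class FluxGrid:
    """A monthly gridded field with coordinates, units and a missing mask.

    Parameters
    ----------
    variable_name : str
        Name of the physical quantity (e.g. ``"GPP"``, ``"NEE"``, ``"T"``).
    values : ndarray, shape (n_time, n_lat, n_lon)
        Field values; entries under ``missing_mask`` are ignored everywhere.
    time : list of (year, month)
        Consecutive calendar months.
    lat_centers, lon_centers : ndarray
        Cell-centre coordinates; latitude ascending, longitude in
        [-180, 180), both uniformly spaced.
    units : str
        Unit string, preserved verbatim through I/O.
    missing_mask : ndarray of bool, optional
        True where the value is missing.  Defaults to ``~isfinite(values)``.
    sign_convention : str
        Free-text note; for NEE, positive = source to atmosphere.
    """

    variable_name: str
    values: np.ndarray
    time: list[tuple[int, int]]
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    units: str = ""
    missing_mask: np.ndarray | None = None
    sign_convention: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        self.time = [(int(y), int(m)) for y, m in self.time]
        if self.values.ndim != 3:
            raise GridContractError("values must be (time, lat, lon)")
        nt, ny, nx = self.values.shape
        if nt != len(self.time) or ny != self.lat_centers.size or nx != self.lon_centers.size:
            raise GridContractError("values shape does not match coordinates")
        _check_consecutive(self.time)
        _uniform_spacing(self.lat_centers, "latitude")
        _uniform_spacing(self.lon_centers, "longitude")
        if np.any(np.abs(self.lat_centers) > 90):
            raise GridContractError("|lat| must be <= 90")
        if np.any(self.lon_centers < -180) or np.any(self.lon_centers >= 180):
            raise GridContractError("lon centers must lie in [-180, 180)")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise GridContractError("missing_mask shape mismatch")
            if not np.all(np.isfinite(self.values[~self.missing_mask])):
                raise GridContractError("values must be finite where not missing")

    # -- convenience -------------------------------------------------------

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.time})

    @property
    def lat_spacing(self) -> float:
        return float(self.lat_centers[1] - self.lat_centers[0])

    @property
    def lon_spacing(self) -> float:
        return float(self.lon_centers[1] - self.lon_centers[0])

    def data_with_nan(self) -> np.ndarray:
        """Values with missing entries set to NaN (copy)."""
        out = self.values.copy()
        out[self.missing_mask] = np.nan
        return out

    def replace(self, **kw) -> "FluxGrid":
        return dataclasses.replace(self, **kw)

    def time_index(self, year: int, month: int) -> int:
        return self.time.index((year, month))


@dataclass
class RegionMask:
    """Fractional membership weights of grid cells in a named region."""

    name: str
    weights: np.ndarray  # (lat, lon), values in [0, 1]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise GridContractError("mask weights must lie in [0, 1]")
        if not np.any(self.weights > 0):
            raise GridContractError("mask must have at least one positive weight")


@dataclass
class RegionSeries:
    """A regional monthly series: flux totals (PgC month-1) or driver means."""

    region: str
    time: list[tuple[int, int]]
    values: np.ndarray
    units: str = ""
    coverage: np.ndarray = field(default=None)  # fraction of mask weight contributing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_consecutive(self.time)
        if self.coverage is None:
            self.coverage = np.where(np.isfinite(self.values), 1.0, 0.0)


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style, via xarray's scipy backend)
# ---------------------------------------------------------------------------

_LAT_NAMES = ("lat", "latitude")
_LON_NAMES = ("lon", "longitude")


def _find_dim(ds: xr.Dataset, candidates) -> str:
    for c in candidates:
        if c in ds.dims or c in ds.coords:
            return c
    raise GridFormatError(f"no coordinate among {candidates} in file")


def write_gridded(grid: FluxGrid, path) -> None:
    """Write a FluxGrid as CF-style NetCDF (time/lat/lon dims, units, _FillValue)."""
    times = pd.to_datetime([f"{y:04d}-{m:02d}-15" for y, m in grid.time])
    da = xr.DataArray(
        grid.data_with_nan(),
        dims=("time", "lat", "lon"),
        coords={"time": times, "lat": grid.lat_centers, "lon": grid.lon_centers},
        name=grid.variable_name,
        attrs={"units": grid.units, "sign_convention": grid.sign_convention},
    )
    ds = da.to_dataset()
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    enc = {grid.variable_name: {"_FillValue": np.float64(-9.0e33), "dtype": "float64"}}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_gridded(path, variable: str) -> FluxGrid:
    """Read one variable from a CF-style NetCDF file into a FluxGrid.

    Longitudes given in [0, 360) are remapped to [-180, 180) and the values
    reordered accordingly; latitude is flipped ascending if needed.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if variable not in ds:
        raise GridFormatError(f"variable {variable!r} not found in {path}")
    da = ds[variable]
    lat_name = _find_dim(ds, _LAT_NAMES)
    lon_name = _find_dim(ds, _LON_NAMES)
    if "time" not in da.dims:
        raise GridFormatError("variable lacks a time dimension")
    da = da.transpose("time", lat_name, lon_name)

    t = pd.to_datetime(da["time"].values)
    time = [(int(ts.year), int(ts.month)) for ts in t]
    try:
        _check_consecutive(time)
    except GridContractError as e:
        raise GridContractError(f"non-monthly time axis in {path}: {e}") from e

    lat = da[lat_name].values.astype(float)
    lon = da[lon_name].values.astype(float)
    vals = da.values.astype(float)

    if lat.size > 1 and lat[1] < lat[0]:
        lat = lat[::-1]
        vals = vals[:, ::-1, :]
    # remap longitudes into [-180, 180), reorder ascending
    lon_wrapped = ((lon + 180.0) % 360.0) - 180.0
    order = np.argsort(lon_wrapped)
    lon = lon_wrapped[order]
    vals = vals[:, :, order]

    units = str(da.attrs.get("units", ""))
    sign = str(da.attrs.get("sign_convention", ""))
    return FluxGrid(
        variable_name=variable,
        values=np.where(np.isfinite(vals), vals, np.nan),
        time=time,
        lat_centers=lat,
        lon_centers=lon,
        units=units,
        sign_convention=sign,
    )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _edges(centers: np.ndarray) -> np.ndarray:
    d = centers[1] - centers[0] if centers.size > 1 else 0.0
    return np.concatenate([centers - d / 2.0, [centers[-1] + d / 2.0]])


def cell_areas(
    lat_centers: np.ndarray,
    lon_centers: np.ndarray,
    radius: float = EARTH_RADIUS_M,
) -> np.ndarray:
    """Spherical-quadrilateral cell areas (m2) on a sphere.

    A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)); cells whose edges
    cross a pole are clipped at +-90 degrees.
    """
    lat_centers = np.asarray(lat_centers, dtype=float)
    lon_centers = np.asarray(lon_centers, dtype=float)
    lat_edges = np.clip(_edges(lat_centers), -90.0, 90.0)
    dlon = np.deg2rad(abs(lon_centers[1] - lon_centers[0]) if lon_centers.size > 1 else 360.0)
    band = radius**2 * dlon * np.diff(np.sin(np.deg2rad(lat_edges)))
    return np.repeat(band[:, None], lon_centers.size, axis=1)


def _interval_overlap(edges_a: np.ndarray, edges_b: np.ndarray) -> np.ndarray:
    """Pairwise overlap length of intervals defined by two edge vectors.

    Returns array (len(a)-1, len(b)-1) of overlaps of half-open cells.
    """
    lo = np.maximum(edges_a[:-1, None], edges_b[None, :-1])
    hi = np.minimum(edges_a[1:, None], edges_b[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def _sin_overlap(edges_a: np.ndarray, edges_b: np.ndarray) -> np.ndarray:
    """Pairwise sin-latitude overlap (proportional to band area) of lat cells."""
    a = np.clip(edges_a, -90.0, 90.0)
    b = np.clip(edges_b, -90.0, 90.0)
    lo = np.maximum(a[:-1, None], b[None, :-1])
    hi = np.minimum(a[1:, None], b[None, 1:])
    out = np.sin(np.deg2rad(np.maximum(hi, lo))) - np.sin(np.deg2rad(lo))
    return np.clip(out, 0.0, None)


def area_weighted_regrid(
    grid: FluxGrid,
    target_lat: np.ndarray,
    target_lon: np.ndarray,
    min_coverage: float = 0.5,
) -> FluxGrid:
    """Regrid an intensive field by overlap-area weighting.

    Each target cell is the area-weighted mean of overlapping source cells;
    missing source cells drop out of the weight sum.  A target cell is
    flagged missing when the valid-source covered fraction of its area falls
    below ``min_coverage``.
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)

    # (n_target_lat, n_source_lat) band-area overlaps; (n_t_lon, n_s_lon) lengths
    wlat = _sin_overlap(_edges(target_lat), _edges(grid.lat_centers))
    wlon = _interval_overlap(_edges(target_lon), _edges(grid.lon_centers))
    if wlat.sum() == 0 or wlon.sum() == 0:
        raise GridContractError("target grid does not overlap the source grid")

    vals = grid.data_with_nan()
    valid = np.isfinite(vals).astype(float)
    v0 = np.nan_to_num(vals)

    # weighted sums via separable overlap matrices:
    #   num[t, i, j] = sum_{k,l} wlat[i,k] wlon[j,l] v[t,k,l] valid[t,k,l]
    num = np.einsum("ik,tkl,jl->tij", wlat, v0 * valid, wlon, optimize=True)
    den = np.einsum("ik,tkl,jl->tij", wlat, valid, wlon, optimize=True)
    # full target-cell "area" in the same (sin-lat x degrees-lon) units
    tle = np.clip(_edges(target_lat), -90.0, 90.0)
    band = np.diff(np.sin(np.deg2rad(tle)))
    dlon_t = np.diff(_edges(target_lon))
    full = np.outer(band, dlon_t)[None, :, :]

    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    coverage = np.where(full > 0, den / full, 0.0)
    missing = (coverage < min_coverage) | ~np.isfinite(out)
    out = np.where(missing, np.nan, out)

    if np.all(missing):
        raise GridContractError("regrid produced an empty output (no coverage)")
    return FluxGrid(
        variable_name=grid.variable_name,
        values=out,
        time=list(grid.time),
        lat_centers=target_lat,
        lon_centers=target_lon,
        units=grid.units,
        missing_mask=missing,
        sign_convention=grid.sign_convention,
    )


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


def aggregate_region(grid: FluxGrid, mask: RegionMask, mode: str = "total") -> RegionSeries:
    """Aggregate a gridded field over a region.

    mode "total": sum of value x cell area x weight, converted gC -> PgC
    (for flux densities in gC m-2 month-1, giving PgC month-1).
    mode "mean": area-and-weight-weighted mean (for drivers), original units.

    Missing cells are excluded and the per-month coverage fraction (share of
    the total mask weight contributed by valid cells) is recorded.  A month
    with no valid contribution is flagged missing (NaN), never silently zero.
    """
    if mask.weights.shape != grid.values.shape[1:]:
        raise GridContractError("mask shape does not match grid")
    if mode not in ("total", "mean"):
        raise GridContractError(f"unknown mode {mode!r}")

    area = cell_areas(grid.lat_centers, grid.lon_centers)
    w = area * mask.weights
    vals = grid.data_with_nan()
    valid = np.isfinite(vals)
    wv = np.where(valid, w[None, :, :], 0.0)

    total_w = w.sum()
    contrib_w = wv.sum(axis=(1, 2))
    coverage = contrib_w / total_w

    v0 = np.nan_to_num(vals)
    if mode == "total":
        out = (v0 * wv).sum(axis=(1, 2)) * GC_TO_PGC
        units = "PgC month-1" if "gC" in grid.units else grid.units
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (v0 * wv).sum(axis=(1, 2)) / contrib_w
        units = grid.units
    out = np.where(coverage > 0, out, np.nan)
    return RegionSeries(
        region=mask.name, time=list(grid.time), values=out, units=units, coverage=coverage
    )


def _box_overlap_frac(centers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fraction of each cell's extent lying within [lo, hi]."""
    e = _edges(centers)
    width = e[1:] - e[:-1]
    ov = np.clip(np.minimum(e[1:], hi) - np.maximum(e[:-1], lo), 0.0, None)
    return ov / width


def default_masks(
    grid: FluxGrid,
    lat_bounds: tuple[float, float] = (24.0, 52.0),
    lon_bounds: tuple[float, float] = (-125.0, -65.0),
    split_lon: float = -103.0,
) -> tuple[RegionMask, RegionMask]:
    """Rectangular west/east masks for temperate North America.

    Default domain 24-52N, 125-65W, split at 103W (west: lon < split).
    Cells straddling a boundary receive fractional weights equal to their
    coordinate-overlap fraction, so the two masks are pointwise disjoint.
    """
    lat0, lat1 = lat_bounds
    lon0, lon1 = lon_bounds
    if not (lon0 < split_lon < lon1):
        raise GridContractError("split meridian must lie inside the longitude bounds")
    fl = _box_overlap_frac(grid.lat_centers, lat0, lat1)
    fw = _box_overlap_frac(grid.lon_centers, lon0, split_lon)
    fe = _box_overlap_frac(grid.lon_centers, split_lon, lon1)
    west = RegionMask("west", np.outer(fl, fw))
    east = RegionMask("east", np.outer(fl, fe))
    return west, east
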