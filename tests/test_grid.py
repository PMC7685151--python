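"""Grid data model, I/O, geometry, regridding and regional aggregation."""

import numpy as np
import pytest
import xarray as xr

from fluxiav.grid import (
    EARTH_RADIUS_M,
    FluxGrid,
    GridContractError,
    GridFormatError,
    RegionMask,
    aggregate_region,
    area_weighted_regrid,
    cell_areas,
    default_masks,
    month_range,
    read_gridded,
    write_gridded,
)

from conftest import make_grid


class TestFluxGridContract:
    def test_time_gap_rejected(self):
        grid = make_grid()
        time = list(grid.time)
        time[5] = (2099, 1)
        with pytest.raises(GridContractError):
            FluxGrid("x", grid.values, time, grid.lat_centers, grid.lon_centers)

    def test_nonuniform_spacing_rejected(self):
        grid = make_grid()
        with pytest.raises(GridContractError):
            FluxGrid("x", grid.values, grid.time, np.array([30.0, 34.0, 40.0]), grid.lon_centers)

    def test_nonfinite_unmasked_rejected(self):
        grid = make_grid()
        vals = grid.values.copy()
        vals[0, 0, 0] = np.inf
        with pytest.raises(GridContractError):
            FluxGrid(
                "x", vals, grid.time, grid.lat_centers, grid.lon_centers,
                missing_mask=np.zeros_like(vals, dtype=bool),
            )


class TestIO:
    def test_round_trip_lossless(self, tmp_path):
        grid = make_grid(seed=7)
        grid.values[3, 1, 2] = np.nan  # missing cell survives the trip
        grid.missing_mask[3, 1, 2] = True
        path = tmp_path / "f.nc"
        write_gridded(grid, path)
        back = read_gridded(path, "GPP")
        np.testing.assert_array_equal(back.missing_mask, grid.missing_mask)
        np.testing.assert_array_equal(
            back.values[~back.missing_mask], grid.values[~grid.missing_mask]
        )
        np.testing.assert_array_equal(back.lat_centers, grid.lat_centers)
        np.testing.assert_array_equal(back.lon_centers, grid.lon_centers)
        assert back.time == grid.time
        assert back.units == "gC m-2 month-1"

    def test_lon_0_360_remapped(self, tmp_path):
        # file on [0, 360): values must be reordered to match [-180, 180)
        import pandas as pd

        lon360 = np.array([0.0, 90.0, 180.0, 270.0])
        vals = np.arange(2 * 2 * 4, dtype=float).reshape(2, 2, 4)
        times = pd.to_datetime(["2001-01-15", "2001-02-15"])
        ds = xr.Dataset(
            {"v": (("time", "lat", "lon"), vals)},
            coords={"time": times, "lat": [10.0, 20.0], "lon": lon360},
        )
        path = tmp_path / "l.nc"
        ds.to_netcdf(path, engine="scipy")
        grid = read_gridded(path, "v")
        np.testing.assert_array_equal(grid.lon_centers, [-180.0, -90.0, 0.0, 90.0])
        # direct index arithmetic: new order of original columns is (2, 3, 0, 1)
        np.testing.assert_array_equal(grid.values, vals[:, :, [2, 3, 0, 1]])

    def test_missing_variable_is_format_error(self, tmp_path):
        grid = make_grid()
        path = tmp_path / "f.nc"
        write_gridded(grid, path)
        with pytest.raises(GridFormatError):
            read_gridded(path, "nope")


class TestCellAreas:
    def test_global_sum_is_sphere_area(self):
        lat = np.arange(-88.0, 90.0, 4.0)
        lon = np.arange(-177.5, 180.0, 5.0)
        total = cell_areas(lat, lon).sum()
        sphere = 4 * np.pi * EARTH_RADIUS_M**2
        assert abs(total - sphere) / sphere < 1e-12

    def test_hemispheric_symmetry(self):
        areas = cell_areas(np.array([-40.0, 0.0, 40.0]), np.array([0.0, 40.0]))
        np.testing.assert_allclose(areas[0], areas[2])

    def test_equatorial_cell_matches_quadrature(self):
        # 1x1 degree cell at the equator vs numerical integration of
        # R^2 cos(lat) dlat dlon
        from scipy.integrate import quad

        area = cell_areas(np.array([0.0, 1.0]), np.array([0.0, 1.0]))[0, 0]
        integral, _ = quad(lambda phi: np.cos(phi), np.deg2rad(-0.5), np.deg2rad(0.5))
        expected = EARTH_RADIUS_M**2 * np.deg2rad(1.0) * integral
        np.testing.assert_allclose(area, expected, rtol=1e-10)


class TestRegrid:
    def test_uniform_field_preserved(self):
        grid = make_grid(values=np.full((36, 3, 3), 5.5))
        out = area_weighted_regrid(grid, np.array([32.0, 36.0]), np.array([-107.5, -102.5]))
        np.testing.assert_allclose(out.values, 5.5, rtol=1e-12)

    def test_latitude_field_matches_closed_form_integral(self):
        # source cells carry the exact area-weighted mean of f(lat) =
        # sin(lat) over each cell; nested-target values must then equal the
        # closed-form area-weighted integral of f over the target band:
        # mean = (sin^2(b) - sin^2(a)) / (2 (sin(b) - sin(a)))
        def band_mean(a_deg, b_deg):
            a, b = np.deg2rad(a_deg), np.deg2rad(b_deg)
            return (np.sin(b) ** 2 - np.sin(a) ** 2) / 2 / (np.sin(b) - np.sin(a))

        lat = np.arange(20.5, 40.0, 1.0)
        lon = np.arange(-119.5, -100.0, 1.0)
        cellmeans = np.array([band_mean(c - 0.5, c + 0.5) for c in lat])
        vals = np.tile(cellmeans[None, :, None], (12, 1, lon.size))
        grid = make_grid(values=vals, n_years=1, lat=lat, lon=lon)
        tlat = np.array([25.0, 35.0])  # 10-degree bands with edges 20/30/40
        tlon = np.array([-115.0, -105.0])
        out = area_weighted_regrid(grid, tlat, tlon)
        for i, (p0, p1) in enumerate([(20.0, 30.0), (30.0, 40.0)]):
            np.testing.assert_allclose(out.values[:, i, :], band_mean(p0, p1), rtol=1e-10)

    def test_fully_missing_source_gives_missing_target(self):
        vals = np.full((12, 3, 3), 2.0)
        vals[:, :, 0] = np.nan  # western column entirely missing
        grid = make_grid(values=vals, n_years=1, lon=(-110.0, -105.0, -100.0))
        out = area_weighted_regrid(
            grid, np.array([31.0, 37.0]), np.array([-110.0, -105.0, -100.0])
        )
        assert out.missing_mask[:, :, 0].all()
        assert not out.missing_mask[:, :, 1].any()
        np.testing.assert_allclose(out.values[:, :, 1:], 2.0)

    def test_global_mean_preserved(self, rng):
        # complete field: regridding preserves the area-weighted global mean
        lat = np.arange(-59.0, 60.0, 2.0)
        lon = np.arange(-179.0, 180.0, 2.0)
        vals = rng.normal(size=(12, lat.size, lon.size))
        grid = make_grid(values=vals, n_years=1, lat=lat, lon=lon)
        tlat = np.arange(-57.0, 60.0, 6.0)
        tlon = np.arange(-177.0, 180.0, 6.0)
        out = area_weighted_regrid(grid, tlat, tlon)
        w_src = cell_areas(lat, lon)
        w_tgt = cell_areas(tlat, tlon)
        m_src = (vals[0] * w_src).sum() / w_src.sum()
        m_tgt = (out.values[0] * w_tgt).sum() / w_tgt.sum()
        np.testing.assert_allclose(m_tgt, m_src, rtol=1e-10)

    def test_no_overlap_errors(self):
        grid = make_grid()
        with pytest.raises(GridContractError):
            area_weighted_regrid(grid, np.array([80.0, 84.0]), np.array([100.0, 105.0]))


class TestAggregateRegion:
    def test_uniform_flux_total(self):
        grid = make_grid(values=np.full((36, 3, 3), 2.0))
        w = np.zeros((3, 3))
        w[1, 1] = 1.0
        w[0, 0] = 0.5
        series = aggregate_region(grid, RegionMask("r", w), mode="total")
        areas = cell_areas(grid.lat_centers, grid.lon_centers)
        expected = 2.0 * (areas[1, 1] + 0.5 * areas[0, 0]) * 1e-15
        np.testing.assert_allclose(series.values, expected, rtol=1e-12)
        assert series.units == "PgC month-1"

    def test_mean_mode_on_uniform_driver(self):
        grid = make_grid(values=np.full((36, 3, 3), 283.0), variable="T", units="K")
        series = aggregate_region(grid, RegionMask("r", np.ones((3, 3))), mode="mean")
        np.testing.assert_allclose(series.values, 283.0)
        assert series.units == "K"

    def test_matches_explicit_loop(self, rng):
        grid = make_grid(seed=3)
        grid.values[4, 2, 1] = np.nan
        grid.missing_mask[4, 2, 1] = True
        weights = rng.uniform(size=(3, 3))
        series = aggregate_region(grid, RegionMask("r", weights), mode="total")
        areas = cell_areas(grid.lat_centers, grid.lon_centers)
        for t in range(len(grid.time)):
            acc = 0.0
            for i in range(3):
                for j in range(3):
                    if not grid.missing_mask[t, i, j]:
                        acc += grid.values[t, i, j] * areas[i, j] * weights[i, j]
            np.testing.assert_allclose(series.values[t], acc * 1e-15, rtol=1e-12)

    def test_linearity_in_field(self, rng):
        f = make_grid(seed=1)
        g = make_grid(seed=2)
        h = make_grid(values=f.values + g.values)
        mask = RegionMask("r", rng.uniform(size=(3, 3)))
        sf = aggregate_region(f, mask).values
        sg = aggregate_region(g, mask).values
        sh = aggregate_region(h, mask).values
        np.testing.assert_allclose(sh, sf + sg, rtol=1e-10)

    def test_all_missing_month_flagged(self):
        vals = np.full((36, 3, 3), 1.0)
        vals[7] = np.nan
        grid = make_grid(values=vals)
        series = aggregate_region(grid, RegionMask("r", np.ones((3, 3))))
        assert np.isnan(series.values[7])
        assert series.coverage[7] == 0.0
        assert np.isfinite(series.values[6])


class TestDefaultMasks:
    def make_4x5(self):
        lat = np.arange(26.0, 52.0, 4.0)
        lon = np.arange(-122.5, -60.0, 5.0)
        vals = np.zeros((12, lat.size, lon.size))
        return make_grid(values=vals, n_years=1, lat=lat, lon=lon)

    def test_clear_west_and_east_cells(self):
        grid = self.make_4x5()
        west, east = default_masks(grid)
        i = np.where(grid.lat_centers == 38.0)[0][0]
        jw = np.where(grid.lon_centers == -112.5)[0][0]
        je = np.where(grid.lon_centers == -77.5)[0][0]
        assert west.weights[i, jw] == 1.0 and east.weights[i, jw] == 0.0
        assert east.weights[i, je] == 1.0 and west.weights[i, je] == 0.0

    def test_straddling_cell_split_by_overlap(self):
        grid = self.make_4x5()
        west, east = default_masks(grid)
        # cell centred at -102.5 spans [-105, -100): 2/5 west of -103
        j = np.where(grid.lon_centers == -102.5)[0][0]
        i = 2
        np.testing.assert_allclose(west.weights[i, j], 0.4)
        np.testing.assert_allclose(east.weights[i, j], 0.6)
        np.testing.assert_allclose(west.weights[i, j] + east.weights[i, j], 1.0)

    def test_masks_disjoint_on_edge_aligned_split(self):
        # with the split on a cell edge no cell belongs to both regions
        grid = self.make_4x5()
        west, east = default_masks(grid, split_lon=-105.0)
        assert np.all(west.weights * east.weights == 0.0)

    def test_no_double_counting_with_fractional_split(self):
        grid = self.make_4x5()
        west, east = default_masks(grid)
        assert np.all(west.weights + east.weights <= 1.0 + 1e-12)

    def test_split_outside_domain_errors(self):
        grid = self.make_4x5()
        with pytest.raises(GridContractError):
            default_masks(grid, split_lon=-130.0)


def test_month_range_wraps_years():
    assert month_range((2001, 11), 3) == [(2001, 11), (2001, 12), (2002, 1)]
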