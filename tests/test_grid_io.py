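"""Grid geometry, cell indexing, resampling and raster/NetCDF round-trips."""

import numpy as np
import pytest
import xarray as xr

from coralhab import (
    DepthInterval,
    Grid,
    ZBinnedField,
    depth_levels_to_intervals,
    read_raster,
    read_zbinned,
    resample_nearest,
    write_raster,
    write_zbinned,
)
from coralhab.grid import normalize_lon


class TestGridGeometry:
    def test_cell_index_at_center(self, grid_factory):
        g = grid_factory(np.zeros((4, 5)))
        lon, lat = g.cell_center(0, 0)
        assert g.cell_index(lon, lat) == (0, 0)

    def test_cell_index_edge_point_is_deterministic(self, grid_factory):
        # point on the shared edge of cells (0,0)/(0,1): belongs to the
        # cell whose half-open footprint [west, east) contains it
        g = grid_factory(np.zeros((4, 5)), lon0=0.0, lat0=10.0, cell=0.5)
        assert g.cell_index(0.5, 9.75) == (0, 1)
        # shared horizontal edge: [north, south) half-open
        assert g.cell_index(0.25, 9.5) == (1, 0)

    def test_cell_index_outside_extent_flags(self, grid_factory):
        g = grid_factory(np.zeros((4, 5)))
        assert g.cell_index(50.0, 9.0) is None
        assert g.cell_index(0.2, 20.0) is None

    def test_cell_center_roundtrip_identity(self, grid_factory, rng):
        g = grid_factory(np.zeros((7, 9)), lon0=-3.0, lat0=42.0, cell=0.25)
        rows = rng.integers(0, 7, size=30)
        cols = rng.integers(0, 9, size=30)
        lon, lat = g.cell_center(rows, cols)
        r2, c2, ok = g.cell_index_array(lon, lat)
        assert ok.all()
        np.testing.assert_array_equal(r2, rows)
        np.testing.assert_array_equal(c2, cols)

    def test_longitudes_normalized(self):
        assert normalize_lon(350.0) == -10.0
        assert normalize_lon(-180.0) == -180.0
        assert normalize_lon(180.0) == -180.0

    def test_rejects_bad_shapes_and_cells(self):
        with pytest.raises(ValueError):
            Grid(np.zeros(5), 0, 0, 0.5)
        with pytest.raises(ValueError):
            Grid(np.zeros((2, 2)), 0, 0, -0.5)


class TestRasterIO:
    def test_ascii_header_echo(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text(
            "ncols 3\nnrows 3\nxllcorner 1.0\nyllcorner 2.0\ncellsize 0.5\n"
            "NODATA_value -9999\n1 2 3\n4 -9999 6\n7 8 9\n"
        )
        g = read_raster(p)
        assert (g.n_rows, g.n_cols) == (3, 3)
        assert g.cell_size_deg == 0.5
        assert g.nodata == -9999
        assert g.lon_origin == 1.0
        assert g.lat_origin == 2.0 + 3 * 0.5
        assert g.values[1, 1] == -9999 and not g.mask[1, 1]

    @pytest.mark.parametrize("fmt,ext", [("ascii_grid", ".asc"), ("geotiff", ".tif")])
    def test_roundtrip(self, tmp_path, rng, fmt, ext):
        vals = rng.normal(size=(6, 7))
        if fmt == "ascii_grid":  # exact only at the written precision
            vals = np.round(vals, 4)
        vals[2, 3] = -9999.0
        g = Grid(vals, -12.25, 48.5, 0.125)
        p = tmp_path / f"g{ext}"
        write_raster(g, p, fmt)
        g2 = read_raster(p, fmt)
        np.testing.assert_array_equal(g2.values, g.values)
        assert g2.geotransform == g.geotransform
        assert g2.nodata == g.nodata

    def test_all_nodata_roundtrip(self, tmp_path):
        g = Grid(np.full((3, 3), -9999.0), 0, 5, 1.0)
        p = tmp_path / "n.asc"
        write_raster(g, p)
        g2 = read_raster(p)
        assert not g2.mask.any()

    def test_rectangular_cells_rejected(self, tmp_path):
        p = tmp_path / "r.asc"
        p.write_text("ncols 2\nnrows 2\ndx 0.5\ndy 0.25\nxllcorner 0\nyllcorner 0\n1 2\n3 4\n")
        with pytest.raises(ValueError, match="rectangular"):
            read_raster(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_raster(tmp_path / "absent.asc")

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "m.asc"
        p.write_text("ncols 2\n1 2 3 4\n")
        with pytest.raises(ValueError):
            read_raster(p)


class TestDepthIntervals:
    def test_midpoint_rule_by_hand(self):
        # depths [0, 50, 100]: boundaries at midpoints 25 and 75; first
        # starts at 0; last extends half the final spacing past 100
        ivs = depth_levels_to_intervals(np.array([0.0, 50.0, 100.0]))
        assert [(iv.top, iv.bottom) for iv in ivs] == [(0, 25), (25, 75), (75, 125)]

    def test_single_level(self):
        ivs = depth_levels_to_intervals(np.array([30.0]), single_level_max_depth=6000)
        assert [(iv.top, iv.bottom) for iv in ivs] == [(0, 6000)]

    def test_unsorted_depths_rejected(self):
        with pytest.raises(ValueError):
            depth_levels_to_intervals(np.array([0.0, 100.0, 50.0]))

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            DepthInterval(50.0, 50.0)
        with pytest.raises(ValueError):
            DepthInterval(-5.0, 50.0)


class TestZBinnedNetCDF:
    def test_read_zbinned_intervals_and_values(self, tmp_path, rng):
        data = rng.normal(size=(3, 4, 5))
        ds = xr.Dataset(
            {"temp": (("depth", "lat", "lon"), data)},
            coords={
                "depth": [0.0, 50.0, 100.0],
                "lat": [3.5, 2.5, 1.5, 0.5],  # north-first
                "lon": [10.5, 11.5, 12.5, 13.5, 14.5],
            },
        )
        p = tmp_path / "t.nc"
        ds.to_netcdf(p, engine="scipy")
        f = read_zbinned(p, "temp")
        assert [(iv.top, iv.bottom) for iv in f.intervals] == [(0, 25), (25, 75), (75, 125)]
        np.testing.assert_allclose(f.slices[1][1].values, data[1])
        g = f.slices[0][1]
        assert g.cell_size_deg == pytest.approx(1.0)
        assert g.lat_origin == pytest.approx(4.0)
        assert g.lon_origin == pytest.approx(10.0)

    def test_south_first_latitudes_are_flipped(self, tmp_path):
        data = np.arange(8, dtype=float).reshape(1, 2, 4)
        ds = xr.Dataset(
            {"s": (("depth", "lat", "lon"), data)},
            coords={"depth": [10.0], "lat": [0.5, 1.5], "lon": [0.5, 1.5, 2.5, 3.5]},
        )
        p = tmp_path / "s.nc"
        ds.to_netcdf(p, engine="scipy")
        f = read_zbinned(p, "s")
        np.testing.assert_allclose(f.slices[0][1].values, data[0, ::-1, :])

    def test_unsorted_depth_rejected(self, tmp_path):
        ds = xr.Dataset(
            {"v": (("depth", "lat", "lon"), np.zeros((2, 2, 2)))},
            coords={"depth": [100.0, 50.0], "lat": [1.5, 0.5], "lon": [0.5, 1.5]},
        )
        p = tmp_path / "u.nc"
        ds.to_netcdf(p, engine="scipy")
        with pytest.raises(ValueError):
            read_zbinned(p, "v")

    def test_missing_depth_coordinate(self, tmp_path):
        ds = xr.Dataset(
            {"v": (("lat", "lon"), np.zeros((2, 2)))},
            coords={"lat": [1.5, 0.5], "lon": [0.5, 1.5]},
        )
        p = tmp_path / "d.nc"
        ds.to_netcdf(p, engine="scipy")
        with pytest.raises((ValueError, KeyError)):
            read_zbinned(p, "v")

    def test_write_read_roundtrip(self, tmp_path, rng, grid_factory):
        g1 = grid_factory(rng.normal(size=(3, 4)))
        g2 = grid_factory(rng.normal(size=(3, 4)))
        f = ZBinnedField("x", [(DepthInterval(0, 50), g1), (DepthInterval(50, 150), g2)])
        p = tmp_path / "rt.nc"
        write_zbinned(f, p)
        f2 = read_zbinned(p, "x")
        np.testing.assert_allclose(f2.slices[0][1].values, g1.values)
        np.testing.assert_allclose(f2.slices[1][1].values, g2.values)


class TestResampleNearest:
    def test_identity_on_same_geotransform(self, grid_factory, rng):
        g = grid_factory(rng.normal(size=(5, 6)))
        out = resample_nearest(g, g.geotransform)
        np.testing.assert_array_equal(out.values, g.values)

    def test_2x_upsampling_repeats_blocks(self, grid_factory):
        g = grid_factory(np.array([[1.0, 2.0], [3.0, 4.0]]), cell=1.0)
        from coralhab import GeoTransform

        target = GeoTransform(g.lon_origin, g.lat_origin, 0.5, 4, 4)
        out = resample_nearest(g, target)
        np.testing.assert_array_equal(out.values, np.kron(g.values, np.ones((2, 2))))

    def test_outside_extent_is_nodata(self, grid_factory):
        g = grid_factory(np.ones((2, 2)), lon0=0.0, lat0=1.0, cell=0.5)
        from coralhab import GeoTransform

        target = GeoTransform(10.0, 50.0, 0.5, 2, 2)
        with pytest.warns(UserWarning, match="no overlap"):
            out = resample_nearest(g, target)
        assert not out.mask.any()

    def test_never_invents_values(self, grid_factory, rng):
        g = grid_factory(rng.integers(0, 5, size=(4, 4)).astype(float), cell=0.4)
        from coralhab import GeoTransform

        target = GeoTransform(g.lon_origin + 0.13, g.lat_origin - 0.07, 0.17, 9, 9)
        out = resample_nearest(g, target)
        assert set(out.values[out.mask]) <= set(g.values.ravel())
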