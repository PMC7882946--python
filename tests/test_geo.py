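"""Track I/O, daily regularization, spherical geometry and raster lookups."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mirounga as mg
from mirounga.geo import KM_PER_DEG, RasterGrid, normalize_lon

lons = st.floats(-720, 720, allow_nan=False)
lats = st.floats(-90, 90, allow_nan=False)


class TestGreatCircle:
    def test_one_degree_of_latitude(self):
        # pi * 6371 / 180 km per degree along a meridian
        assert mg.great_circle_km(70, -49, 70, -50) == pytest.approx(KM_PER_DEG, abs=1e-9)

    def test_antipodal(self):
        assert mg.great_circle_km(0, 0, 180, 0) == pytest.approx(math.pi * 6371.0, abs=1e-6)

    @given(lon1=lons, lat1=lats, lon2=lons, lat2=lats)
    def test_symmetry_and_nonnegativity(self, lon1, lat1, lon2, lat2):
        d12 = mg.great_circle_km(lon1, lat1, lon2, lat2)
        d21 = mg.great_circle_km(lon2, lat2, lon1, lat1)
        assert d12 == pytest.approx(d21, abs=1e-9)
        assert d12 >= 0

    @given(lon=lons, lat=lats)
    def test_zero_at_identical_points(self, lon, lat):
        assert mg.great_circle_km(lon, lat, lon, lat) == 0.0


class TestNormalizeLon:
    def test_convention(self):
        assert normalize_lon(340.0) == pytest.approx(-20.0)
        assert normalize_lon(-180.0) == -180.0
        assert normalize_lon(180.0) == -180.0

    @given(lon=lons)
    def test_idempotent_and_in_range(self, lon):
        x = float(normalize_lon(lon))
        assert -180.0 <= x < 180.0
        assert float(normalize_lon(x)) == pytest.approx(x, abs=1e-9)


class TestRegularizeDaily:
    def test_linear_midpoint(self):
        tr = mg.regularize_daily([(0, 0, -50), (48, 2, -50)])
        assert len(tr) == 3
        assert tr.lon[1] == pytest.approx(1.0)
        assert tr.lat[1] == pytest.approx(-50.0)

    def test_long_gap_days_flagged(self):
        tr = mg.regularize_daily([(0, 0, -50), (240, 5, -50)])
        assert list(tr.gap.astype(int)) == [0] + [1] * 9 + [0]

    def test_antimeridian_short_way(self):
        tr = mg.regularize_daily([(0, 179, -50), (48, -179, -50)])
        # midpoint of the short crossing is the antimeridian itself
        assert tr.lon[1] == pytest.approx(-180.0)

    def test_single_fix_rejected(self):
        with pytest.raises(ValueError):
            mg.regularize_daily([(0, 0, -50)])

    def test_output_inside_fix_bounding_box(self):
        rng = np.random.default_rng(5)
        hours = np.sort(rng.uniform(0, 24 * 30, 200))
        hours[0] = 0.0
        lon = rng.uniform(60, 80, 200)
        lat = rng.uniform(-60, -50, 200)
        tr = mg.regularize_daily(np.column_stack([hours, lon, lat]))
        assert tr.lon.min() >= lon.min() - 1e-9 and tr.lon.max() <= lon.max() + 1e-9
        assert tr.lat.min() >= lat.min() - 1e-9 and tr.lat.max() <= lat.max() + 1e-9
        # length = floor(span in days) + 1
        assert len(tr) == int(math.floor(hours[-1] / 24)) + 1


class TestTrackIO:
    def test_roundtrip_identity(self, tmp_path, small_study):
        path = tmp_path / "tracks.csv"
        mg.write_tracks(small_study.tracks, path)
        back = mg.read_tracks(path)
        assert len(back) == len(small_study.tracks)
        by_id = {t.seal_id: t for t in back}
        for orig in small_study.tracks:
            got = by_id[orig.seal_id]
            np.testing.assert_allclose(got.lon, orig.lon, atol=1e-9)
            np.testing.assert_allclose(got.lat, orig.lat, atol=1e-9)
            np.testing.assert_array_equal(got.t, orig.t)
            np.testing.assert_array_equal(got.gap, orig.gap)

    def test_two_row_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("seal_id,t,doy,lon,lat\ns1,0,10,340,-50\ns1,1,11,341,-50\n")
        (tr,) = mg.read_tracks(p)
        assert len(tr) == 2
        assert tr.lon[0] == pytest.approx(-20.0)  # normalized on read

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("seal_id,t,lon,lat\ns1,0,0,-50\n")
        with pytest.raises(ValueError, match="doy"):
            mg.read_tracks(p)

    def test_duplicate_time_names_seal(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("seal_id,t,doy,lon,lat\nsealX,0,1,0,-50\nsealX,0,1,1,-50\n")
        with pytest.raises(ValueError, match="sealX"):
            mg.read_tracks(p)


class TestMaxDistance:
    def test_stationary_track_is_zero(self):
        tr = mg.Track("s", t=[0, 1, 2], doy=[1, 2, 3], lon=[70, 70, 70], lat=[-49, -49, -49])
        assert mg.max_distance_from_colony(tr, 70, -49) == 0.0

    def test_one_degree_south(self):
        tr = mg.Track("s", t=[0, 1], doy=[1, 2], lon=[70, 70], lat=[-49, -50])
        assert mg.max_distance_from_colony(tr, 70, -49) == pytest.approx(KM_PER_DEG, abs=1e-9)

    def test_monotone_outbound_attains_last_point(self):
        lat = -49 - np.arange(10) * 0.5
        tr = mg.Track("s", t=np.arange(10), doy=np.arange(1, 11), lon=np.full(10, 70.0), lat=lat)
        d_last = mg.great_circle_km(70, lat[-1], 70, -49)
        assert mg.max_distance_from_colony(tr, 70, -49) == pytest.approx(d_last)


class TestRasterLookup:
    def grid(self):
        return RasterGrid(
            lon_axis=[0.0, 1.0, 2.0],
            lat_axis=[-52.0, -51.0, -50.0],
            values=np.arange(9, dtype=float).reshape(3, 3),
            kind="bathymetry_depth_m",
        )

    def test_exact_cell_centre(self):
        g = self.grid()
        assert g.lookup(1.0, -51.0) == 4.0

    def test_boundary_ties_to_lower_index(self):
        g = self.grid()
        assert g.lookup(0.5, -52.0) == 0.0   # lon tie -> lower lon index
        assert g.lookup(0.0, -51.5) == 0.0   # lat tie -> lower lat index

    def test_constant_grid_everywhere(self):
        g = RasterGrid([0, 1, 2], [-52, -51, -50], np.full((3, 3), 7.0), "bathymetry_depth_m")
        for lon, lat in [(0.1, -51.9), (1.7, -50.2), (2.0, -50.0)]:
            assert g.lookup(lon, lat) == 7.0

    def test_out_of_bounds_names_point(self):
        with pytest.raises(ValueError, match="lon=5"):
            self.grid().lookup(5.0, -51.0)

    def test_lookup_many_matches_scalar(self):
        g = self.grid()
        rng = np.random.default_rng(0)
        lon = rng.uniform(0, 2, 50)
        lat = rng.uniform(-52, -50, 50)
        many = g.lookup_many(lon, lat)
        singles = [g.lookup(x, y) for x, y in zip(lon, lat)]
        np.testing.assert_array_equal(many, singles)


class TestRasterIO:
    def test_netcdf_roundtrip(self, tmp_path, bathy):
        from mirounga.geo import read_raster, write_raster

        p = tmp_path / "b.nc"
        write_raster(bathy, p)
        back = read_raster(p)
        np.testing.assert_array_equal(back.values, bathy.values)
        assert back.kind == bathy.kind

    def test_ice_series_roundtrip(self, tmp_path, small_config):
        from mirounga.geo import read_ice_series, write_ice_series

        ice = mg.make_ice_series(small_config)
        p = tmp_path / "ice.nc"
        write_ice_series(ice, p)
        back = read_ice_series(p)
        np.testing.assert_array_equal(back[180].values, ice[180].values)
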