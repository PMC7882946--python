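"""Habitat masks, ice membership, stage windows, dominant habitat, size matching."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mirounga as mg
from mirounga.habitats import Habitat, dominant_habitat, stage_windows


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "lat, lon, depth, expected",
        [
            (-65, 100, 400, Habitat.ANT_SHELF),
            (-50, 68, 500, Habitat.KERG_PLATEAU),
            (-50, 80, 3000, Habitat.OCEANIC_EAST),
            (-50, 60, 3000, Habitat.OCEANIC_WEST),
            (-65, 100, 1500, Habitat.ANT_SHELF),   # shelf precedence over oceanic
            (-50, 70, 3000, Habitat.OCEANIC_EAST),  # 70E boundary -> east
            (-60, 68, 500, Habitat.KERG_PLATEAU),   # -60 boundary -> northern rule set
            (-50, 60, -10, Habitat.OTHER),          # land never raises
            (-50, 60, float("nan"), Habitat.OTHER),
        ],
    )
    def test_examples(self, lat, lon, depth, expected):
        assert mg.classify_location(lat, lon, depth) is expected

    @given(
        lat=st.floats(-90, 90),
        lon=st.floats(-180, 180, exclude_max=True),
        depth=st.floats(-11000, 11000, allow_nan=False),
    )
    def test_total_single_valued(self, lat, lon, depth):
        label = mg.classify_location(lat, lon, depth)
        assert isinstance(label, Habitat)

    def test_partition_on_global_grid(self):
        lon, lat = np.meshgrid(np.arange(-180.0, 180.0), np.arange(-89.0, 90.0))
        for depth in (100.0, 500.0, 1500.0, 2500.0, 3500.0):
            labels = mg.classify_locations(lat.ravel(), lon.ravel(), np.full(lat.size, depth))
            assert labels.shape == (lat.size,)
            assert all(isinstance(l, Habitat) for l in labels)


class TestInIce:
    def test_threshold_strict(self):
        assert mg.in_ice(0.16)
        assert not mg.in_ice(0.15)
        assert not mg.in_ice(0.0)

    def test_nan_counts_as_not_in_ice(self):
        assert not bool(mg.in_ice(float("nan")))


class TestStageWindows:
    def test_male_windows(self):
        w = stage_windows("male")
        assert w.windows == ((21, 87), (146, 212), (213, 279))

    def test_female_windows(self):
        w = stage_windows("female")
        assert w.windows == ((21, 87), (88, 154), (155, 221))

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_each_window_spans_67_inclusive_days(self, sex):
        for lo, hi in stage_windows(sex).windows:
            assert hi - lo + 1 == 67

    def test_unknown_sex(self):
        with pytest.raises(ValueError):
            stage_windows("hermaphrodite")

    def test_stage_of_day(self):
        w = stage_windows("male")
        assert list(w.stage_of([20, 21, 87, 88, 146, 212, 213, 279, 280])) == [
            0, 1, 1, 0, 2, 2, 3, 3, 0,
        ]


def _flat_grid(depth, lon0=60.0, lat0=-55.0):
    lon = np.arange(lon0 - 5, lon0 + 5.5, 1.0)
    lat = np.arange(lat0 - 5, lat0 + 5.5, 1.0)
    return mg.RasterGrid(lon, lat, np.full((len(lat), len(lon)), depth), "bathymetry_depth_m")


def _track_days(days, lon, lat, sex_doy0=1):
    n = len(days)
    return mg.Track("s", t=np.asarray(days, float), doy=np.arange(1, n + 1),
                    lon=np.full(n, lon), lat=np.full(n, lat))


class TestDominantHabitat:
    def _mixed_track(self, n_kp=40, n_ant=20, n_oe=6):
        # KP: shallow north; ANT: shallow south; OE: deep east -- via position
        lon = [68.0] * n_kp + [100.0] * n_ant + [100.0] * n_oe
        lat = [-50.0] * n_kp + [-65.0] * n_ant + [-55.0] * n_oe
        days = np.arange(21, 21 + n_kp + n_ant + n_oe, dtype=float)
        return mg.Track("s", t=days, doy=np.arange(1, len(days) + 1), lon=lon, lat=lat)

    def _varied_bathy(self):
        lon = np.arange(40.0, 111.0, 1.0)
        lat = np.arange(-70.0, -44.0, 1.0)
        lon_g, lat_g = np.meshgrid(lon, lat)
        depth = np.where(lat_g <= -60, 500.0, np.where(lon_g < 80, 500.0, 3000.0))
        return mg.RasterGrid(lon, lat, depth, "bathymetry_depth_m")

    def test_mixed_occupancy_percentages(self):
        occ = dominant_habitat(self._mixed_track(), self._varied_bathy(), stage_windows("female"), 1)
        assert occ.n_days_classified == 66
        assert occ.dominant is Habitat.KERG_PLATEAU
        assert occ.percentages[Habitat.KERG_PLATEAU] == pytest.approx(100 * 40 / 66)
        assert occ.percentages[Habitat.KERG_PLATEAU] == pytest.approx(60.61, abs=0.01)
        assert not occ.tie

    def test_percentages_sum_to_100(self):
        occ = dominant_habitat(self._mixed_track(), self._varied_bathy(), stage_windows("female"), 1)
        assert sum(occ.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_habitat_track(self):
        tr = _track_days(np.arange(21, 88), 68.0, -50.0)
        occ = dominant_habitat(tr, _flat_grid(500.0, 68.0, -50.0), stage_windows("female"), 1)
        assert occ.dominant is Habitat.KERG_PLATEAU
        assert occ.percentages[Habitat.KERG_PLATEAU] == pytest.approx(100.0)

    def test_tie_broken_by_label_order_and_flagged(self):
        # 33 days ANT_SHELF, 33 days KERG_PLATEAU within one stage window
        lon = [100.0] * 33 + [68.0] * 33
        lat = [-65.0] * 33 + [-50.0] * 33
        days = np.arange(21, 87, dtype=float)
        tr = mg.Track("s", t=days, doy=np.arange(1, 67), lon=lon, lat=lat)
        occ = dominant_habitat(tr, self._varied_bathy(), stage_windows("female"), 1)
        assert occ.dominant is Habitat.ANT_SHELF
        assert occ.tie

    def test_no_classified_days_marks_empty(self):
        tr = _track_days(np.arange(0, 10), 68.0, -50.0)  # before stage 1
        occ = dominant_habitat(tr, _flat_grid(500.0, 68.0, -50.0), stage_windows("female"), 1)
        assert occ.n_days_classified == 0
        assert occ.dominant is None


class TestSizeMatch:
    def test_percentile_bounds_on_even_sequence(self):
        # 100 evenly spaced female lengths on [2, 3]: linear-interpolated
        # 1st/99th percentiles are 2 + 0.99*(1/99) = 2.01 and 2.99
        lengths = np.linspace(2.0, 3.0, 100)
        females = {f"f{i}": float(x) for i, x in enumerate(lengths)}
        males = {"m_mid": 2.5, "m_big": 3.1, "m_small": 1.9}
        keep_f, keep_m, (lo, hi) = mg.size_match(females, males)
        assert lo == pytest.approx(2.01)
        assert hi == pytest.approx(2.99)
        assert keep_m == {"m_mid"}
        assert len(keep_f) == 98

    def test_all_equal_lengths_retains_everyone(self):
        females = {f"f{i}": 2.4 for i in range(10)}
        males = {f"m{i}": 2.4 for i in range(5)}
        keep_f, keep_m, _ = mg.size_match(females, males)
        assert len(keep_f) == 10 and len(keep_m) == 5

    def test_male_outside_female_range_excluded(self):
        females = {f"f{i}": x for i, x in enumerate([2.2, 2.3, 2.4, 2.5])}
        keep_f, keep_m, _ = mg.size_match(females, {"shorty": 2.0})
        assert keep_m == set()

    def test_requires_three_females(self):
        with pytest.raises(ValueError):
            mg.size_match({"f1": 2.0, "f2": 2.1}, {})
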