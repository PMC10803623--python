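import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import LineString, Point, Polygon

from littoral import fetch as F
from littoral.geometry import LakeGeometry, Transect

from conftest import circle_ring


def ldm_oracle(directions_deg) -> float:
    """Resultant-vector circular mean via the two-argument arctangent."""
    th = np.radians(np.asarray(directions_deg, dtype=float))
    return math.degrees(math.atan2(np.sin(th).sum(), np.cos(th).sum())) % 360.0


class TestCastFetchRays:
    def test_circle_chords(self):
        # anchor on a circle, normal through the center: chord = 2R cos(offset)
        geom = LakeGeometry(shoreline=Polygon(circle_ring(500.0, n=2880)), z_max=10.0)
        tr = Transect(transect_id="T", anchor=Point(500.0, 0.0), onshore_normal_deg=270.0)
        rays = F.cast_fetch_rays(tr, geom)
        expected = [2 * 0.5 * math.cos(math.radians(a)) for a in (45, 22.5, 0, 22.5, 45)]
        assert rays == pytest.approx(expected, abs=2e-3)

    def test_square_mid_edge_middle_ray(self):
        side = 800.0
        square = Polygon([(0, 0), (side, 0), (side, side), (0, side)])
        geom = LakeGeometry(shoreline=square, z_max=5.0)
        tr = Transect(transect_id="T", anchor=Point(side / 2, 0.0), onshore_normal_deg=0.0)
        rays = F.cast_fetch_rays(tr, geom)
        assert rays[2] == pytest.approx(side / 1000.0, abs=1e-9)

    def test_island_blocks_middle_ray(self):
        square = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        island = Polygon([(450, 280), (550, 280), (550, 320), (450, 320)])
        geom = LakeGeometry(shoreline=square, islands=[island], z_max=5.0)
        tr = Transect(transect_id="T", anchor=Point(500.0, 0.0), onshore_normal_deg=0.0)
        rays = F.cast_fetch_rays(tr, geom)
        assert rays[2] == pytest.approx(0.280, abs=1e-9)

    def test_circular_symmetry_of_effective_fetch(self, conic_lake):
        geom, _grid, transects = conic_lake
        fetches = [F.effective_fetch(F.cast_fetch_rays(tr, geom)) for tr in transects]
        assert max(fetches) - min(fetches) < 1e-9


class TestEffectiveFetch:
    def test_constant_rays(self):
        assert F.effective_fetch([1.0] * 5) == pytest.approx(1.0, abs=1e-12)

    def test_circle_value(self):
        rays = [0.70711, 0.92388, 1.0, 0.92388, 0.70711]
        assert F.effective_fetch(rays) == pytest.approx(0.86981, abs=1e-5)

    def test_single_middle_ray(self):
        assert F.effective_fetch([0, 0, 1.0, 0, 0]) == pytest.approx(1 / 4.26198, abs=1e-5)

    def test_weights_follow_cosine_rule(self):
        assert F.FETCH_WEIGHTS[1] == pytest.approx(math.cos(math.radians(22.5)), abs=5e-6)
        assert F.FETCH_WEIGHTS[0] == pytest.approx(math.cos(math.radians(45.0)), abs=5e-6)
        assert sum(F.FETCH_WEIGHTS) == pytest.approx(4.26198, abs=1e-5)

    def test_wrong_ray_count_rejected(self):
        with pytest.raises(ValueError):
            F.effective_fetch([1.0, 2.0, 3.0])

    @given(st.lists(st.floats(min_value=0, max_value=10), min_size=5, max_size=5))
    def test_bounded_by_extremes_and_symmetric(self, rays):
        f = F.effective_fetch(rays)
        assert min(rays) - 1e-12 <= f <= max(rays) + 1e-12
        mirrored = rays[::-1]
        assert F.effective_fetch(mirrored) == pytest.approx(f, abs=1e-12)


class TestLinearDirectionalMean:
    @pytest.mark.parametrize(
        "dirs, expected",
        [
            ([10.0, 350.0], 0.0),
            ([90.0, 180.0], 135.0),   # sum sin >= 0, sum cos < 0: 180 - |LDM|
            ([200.0, 340.0], 270.0),  # sum sin < 0: 360 - |LDM| branch limit
            ([90.0], 90.0),
            ([45.0, 45.0, 45.0], 45.0),
        ],
    )
    def test_quadrant_branches(self, dirs, expected):
        assert F.linear_directional_mean(dirs) == pytest.approx(expected, abs=1e-9)

    def test_opposed_pair_undefined(self):
        with pytest.raises(F.UndefinedMeanError):
            F.linear_directional_mean([0.0, 180.0])

    def test_agrees_with_resultant_vector_oracle(self, rng):
        for _ in range(2000):
            n = int(rng.integers(1, 40))
            dirs = rng.uniform(0.0, 360.0, size=n)
            got = F.linear_directional_mean(dirs)
            want = ldm_oracle(dirs)
            diff = abs(got - want) % 360.0
            assert min(diff, 360.0 - diff) < 1e-9


class TestDailyWindSummary:
    def test_constant_day(self):
        ts = pd.date_range("2015-06-01", periods=24, freq="h")
        wind = pd.DataFrame({"timestamp": ts, "direction_deg": 90.0, "speed_ms": 5.0})
        daily = F.daily_wind_summary(wind)
        assert len(daily) == 1
        assert daily.loc[0, "direction_deg"] == pytest.approx(90.0)
        assert daily.loc[0, "speed_ms"] == pytest.approx(5.0)

    def test_speed_mean_and_direction_ldm(self):
        ts = pd.date_range("2015-06-01", periods=2, freq="h")
        wind = pd.DataFrame({"timestamp": ts, "direction_deg": [10.0, 350.0], "speed_ms": [2.0, 4.0]})
        daily = F.daily_wind_summary(wind)
        assert daily.loc[0, "direction_deg"] == pytest.approx(0.0, abs=1e-9)
        assert daily.loc[0, "speed_ms"] == pytest.approx(3.0)

    def test_matches_scalar_ldm_per_day(self, rng):
        ts = pd.date_range("2015-01-01", periods=24 * 20, freq="h")
        wind = pd.DataFrame(
            {"timestamp": ts,
             "direction_deg": rng.uniform(0, 360, size=len(ts)),
             "speed_ms": rng.uniform(0, 10, size=len(ts))}
        )
        daily = F.daily_wind_summary(wind)
        for day, grp in wind.groupby(wind["timestamp"].dt.date):
            want = F.linear_directional_mean(grp["direction_deg"].to_numpy())
            got = float(daily.loc[daily["date"] == day, "direction_deg"].iloc[0])
            assert got == pytest.approx(want, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            F.daily_wind_summary(pd.DataFrame(columns=["timestamp", "direction_deg", "speed_ms"]))


class TestTowardShare:
    def _daily(self, directions):
        return pd.DataFrame(
            {"date": pd.date_range("2015-01-01", periods=len(directions)).date,
             "direction_deg": directions, "speed_ms": 4.0}
        )

    def test_all_onshore(self):
        tr = Transect(transect_id="T", anchor=Point(0, 0), onshore_normal_deg=90.0)
        assert F.toward_share(self._daily([90.0] * 10), tr) == 1.0

    def test_all_offshore(self):
        tr = Transect(transect_id="T", anchor=Point(0, 0), onshore_normal_deg=90.0)
        assert F.toward_share(self._daily([270.0] * 10), tr) == 0.0

    def test_uniform_quarter(self, rng):
        tr = Transect(transect_id="T", anchor=Point(0, 0), onshore_normal_deg=200.0)
        dirs = rng.uniform(0, 360, size=20000)
        assert F.toward_share(self._daily(dirs), tr) == pytest.approx(0.25, abs=0.02)

    def test_to_convention_flips_sector(self):
        tr = Transect(transect_id="T", anchor=Point(0, 0), onshore_normal_deg=90.0)
        daily = self._daily([270.0] * 10)
        assert F.toward_share(daily, tr, convention="to") == 1.0


class TestExposure:
    def test_zero_when_no_toward_days(self):
        assert F.exposure(1.0, 0.0, 4.0, 1.0) == 0.0

    def test_hand_values(self):
        assert F.exposure(1.0, 0.5, 4.0, 1.0) == pytest.approx(math.log(3.0), abs=1e-9)
        assert F.exposure(1.0, 0.5, 4.0, 2.0) == pytest.approx(math.log(1.5), abs=1e-9)

    def test_log_base_option(self):
        assert F.exposure(1.0, 0.5, 4.0, 1.0, log_base=10) == pytest.approx(math.log10(3.0))

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            F.exposure(1.0, 0.5, 4.0, 0.0)

    @given(
        st.floats(min_value=0.01, max_value=5.0),
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=0.01, max_value=15.0),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_monotone_in_each_argument(self, f, w, h, d):
        e = F.exposure(f, w, h, d)
        assert F.exposure(f * 1.1, w, h, d) > e
        assert F.exposure(f, min(w * 1.1, 1.0), h, d) >= e
        assert F.exposure(f, w, h * 1.1, d) > e
        assert F.exposure(f, w, h, d * 1.1) < e
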