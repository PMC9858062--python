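import datetime as dt

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import hazsense as hz
from hazsense.footfall import coverage_share
from hazsense.geo import offset_lonlat


def stay_at(lon, lat, when="2020-01-05T10:00:00", user="u1"):
    t = pd.Timestamp(when)
    return {
        "user_id": user,
        "centroid_lon": lon,
        "centroid_lat": lat,
        "start_time": t,
        "end_time": t + pd.Timedelta(minutes=10),
        "duration_s": 600.0,
        "n_points": 4,
    }


class TestAssignment:
    def test_centroid_inside_cell(self, grid3):
        lon, lat = offset_lonlat(-0.1276, 51.5072, 750, 250)  # cell row 0, col 1
        assigned = hz.assign_stays_to_units(pd.DataFrame([stay_at(lon, lat)]), grid3)
        assert assigned["unit_id"].iloc[0] == "u0_1"

    def test_centroid_outside_grid_unassigned(self, grid3):
        lon, lat = offset_lonlat(-0.1276, 51.5072, -900, -900)
        assigned = hz.assign_stays_to_units(pd.DataFrame([stay_at(lon, lat)]), grid3)
        assert pd.isna(assigned["unit_id"].iloc[0])
        assert assigned.attrs["n_unassigned"] == 1

    def test_boundary_point_assigned_exactly_once(self, grid3):
        # a point on the shared edge between u0_0 and u0_1
        edge = grid3.loc[grid3["unit_id"] == "u0_0", "geometry"].iloc[0]
        xs = sorted({round(c[0], 12) for c in edge.exterior.coords})
        mid_lat = (edge.bounds[1] + edge.bounds[3]) / 2
        assigned = hz.assign_stays_to_units(pd.DataFrame([stay_at(xs[-1], mid_lat)]), grid3)
        assert assigned["unit_id"].iloc[0] in {"u0_0", "u0_1"}  # one unit, deterministically
        again = hz.assign_stays_to_units(pd.DataFrame([stay_at(xs[-1], mid_lat)]), grid3)
        assert assigned["unit_id"].iloc[0] == again["unit_id"].iloc[0]

    def test_overlapping_units_fatal(self):
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        shifted = Polygon([(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)])
        units = pd.DataFrame({"unit_id": ["a", "b"], "geometry": [square, shifted]})
        with pytest.raises(ValueError):
            hz.assign_stays_to_units(pd.DataFrame([stay_at(0.2, 0.2)]), units)

    def test_ledger_agreement_at_scale(self, demo14):
        stays = hz.detect_stays_all(demo14["points"], hz.StayParams())
        assigned = hz.assign_stays_to_units(stays, demo14["units"])
        merged = assigned.sort_values(["user_id", "start_time"]).reset_index()
        ledger = demo14["ledger"].sort_values(["user_id", "start_time"]).reset_index()
        assert (merged["unit_id"].to_numpy() == ledger["unit_id"].to_numpy()).all()


class TestFootfallMatrix:
    def test_no_stays_gives_zero_matrix(self, grid3):
        empty = pd.DataFrame(columns=list(stay_at(0, 0)) + ["unit_id"])
        matrix = hz.build_footfall_matrix(empty, grid3["unit_id"], dt.date(2020, 1, 1), dt.date(2020, 1, 14))
        assert matrix.shape == (9, 14)
        assert (matrix == 0).all().all()

    def test_single_stay_single_cell(self, grid3):
        stays = pd.DataFrame([stay_at(0, 0)])
        stays["unit_id"] = "u1_1"
        matrix = hz.build_footfall_matrix(stays, grid3["unit_id"], dt.date(2020, 1, 1), dt.date(2020, 1, 14))
        assert matrix.to_numpy().sum() == 1
        assert matrix.loc["u1_1", pd.Timestamp("2020-01-05")] == 1

    def test_column_sums_match_ledger(self, demo14, mini_calendar):
        stays = hz.detect_stays_all(demo14["points"], hz.StayParams())
        assigned = hz.assign_stays_to_units(stays, demo14["units"])
        matrix = hz.build_footfall_matrix(
            assigned, demo14["units"]["unit_id"],
            mini_calendar[0].start_date, mini_calendar[-1].end_date,
        )
        per_day = demo14["ledger"].groupby("date").size()
        for date, count in per_day.items():
            assert matrix[pd.Timestamp(date)].sum() == count
        assert matrix.to_numpy().sum() == len(demo14["ledger"])

    def test_out_of_range_strict_vs_clipped(self, grid3):
        stays = pd.DataFrame([stay_at(0, 0, when="2021-06-01T10:00:00")])
        stays["unit_id"] = "u0_0"
        with pytest.raises(ValueError):
            hz.build_footfall_matrix(stays, grid3["unit_id"], dt.date(2020, 1, 1), dt.date(2020, 1, 14))
        matrix = hz.build_footfall_matrix(
            stays, grid3["unit_id"], dt.date(2020, 1, 1), dt.date(2020, 1, 14), strict=False
        )
        assert matrix.to_numpy().sum() == 0

    def test_unique_user_variant_counts_users_once(self, grid3):
        rows = [stay_at(0, 0, user="a"), stay_at(0, 0, "2020-01-05T14:00:00", user="a")]
        stays = pd.DataFrame(rows)
        stays["unit_id"] = "u0_0"
        by_stays = hz.build_footfall_matrix(stays, grid3["unit_id"], dt.date(2020, 1, 1), dt.date(2020, 1, 14))
        by_users = hz.build_footfall_matrix(
            stays, grid3["unit_id"], dt.date(2020, 1, 1), dt.date(2020, 1, 14), count="users"
        )
        assert by_stays.to_numpy().sum() == 2
        assert by_users.to_numpy().sum() == 1


class TestRecoveryIndex:
    def make_matrix(self, totals, start=dt.date(2020, 1, 1)):
        dates = pd.date_range(start, periods=len(totals), freq="D")
        return pd.DataFrame([totals], index=pd.Index(["u"], name="unit_id"), columns=dates)

    def test_constant_totals_give_100(self):
        matrix = self.make_matrix([10] * 90)
        rec = hz.recovery_index(matrix, dt.date(2020, 1, 1), dt.date(2020, 1, 30))
        assert np.allclose(rec.daily, 100.0)
        assert np.allclose(rec.rolling, 100.0)

    def test_halved_totals_give_50(self):
        matrix = self.make_matrix([10] * 30 + [5] * 30)
        rec = hz.recovery_index(matrix, dt.date(2020, 1, 1), dt.date(2020, 1, 30))
        assert np.allclose(rec.daily.iloc[30:], 50.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        totals = rng.integers(5, 50, size=120).tolist()
        a = hz.recovery_index(self.make_matrix(totals), dt.date(2020, 1, 1), dt.date(2020, 1, 31))
        b = hz.recovery_index(
            self.make_matrix([7 * t for t in totals]), dt.date(2020, 1, 1), dt.date(2020, 1, 31)
        )
        assert np.allclose(a.daily, b.daily)

    def test_benchmark_window_day_count(self):
        matrix = self.make_matrix([10] * 120)
        rec = hz.recovery_index(matrix, dt.date(2020, 1, 1), dt.date(2020, 2, 29))
        assert rec.n_benchmark_days == 60

    def test_zero_benchmark_fatal(self):
        matrix = self.make_matrix([0] * 30 + [5] * 30)
        with pytest.raises(ValueError):
            hz.recovery_index(matrix, dt.date(2020, 1, 1), dt.date(2020, 1, 15))

    def test_rolling_head_uses_available_days(self):
        matrix = self.make_matrix([10, 20] + [10] * 58)
        rec = hz.recovery_index(matrix, dt.date(2020, 1, 1), dt.date(2020, 2, 29))
        assert rec.rolling.iloc[0] == rec.daily.iloc[0]
        assert rec.rolling.iloc[1] == pytest.approx((rec.daily.iloc[0] + rec.daily.iloc[1]) / 2)


def test_coverage_share():
    assert coverage_share(1, 4) == 25.0
    with pytest.raises(ValueError):
        coverage_share(1, 0)
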