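"""Aggregation of gridded concentrations to area-month exposure metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stcar import (
    METRICS,
    aggregate_metrics,
    daily_to_monthly,
    hourly_to_daily,
    spatial_aggregate,
    standardize_metric,
)


def hourly_frame(values, cell="c1", day="2007-01-01"):
    times = pd.date_range(day, periods=len(values), freq="h")
    return pd.DataFrame(
        {"cell_id": cell, "pollutant": "NO2", "time": times, "value": values}
    )


class TestHourlyToDaily:
    def test_constant_hours(self):
        out = hourly_to_daily(hourly_frame([7.0] * 24))
        assert out["daily_mean"].iloc[0] == 7.0
        assert out["daily_max"].iloc[0] == 7.0

    def test_two_hours(self):
        out = hourly_to_daily(hourly_frame([0.0, 10.0]))
        assert out["daily_mean"].iloc[0] == 5.0
        assert out["daily_max"].iloc[0] == 10.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 60, size=24)
        out = hourly_to_daily(hourly_frame(vals))
        s = m = 0.0
        for v in vals:  # brute-force oracle
            s += v
            m = max(m, v)
        assert out["daily_mean"].iloc[0] == pytest.approx(s / 24)
        assert out["daily_max"].iloc[0] == pytest.approx(m)

    def test_negative_value_is_error(self):
        with pytest.raises(ValueError):
            hourly_to_daily(hourly_frame([1.0, -2.0]))


def daily_frame(means, maxes, cell="c1", start="2007-01-01"):
    dates = pd.date_range(start, periods=len(means), freq="D")
    return pd.DataFrame(
        {
            "cell_id": cell,
            "pollutant": "NO2",
            "date": dates,
            "daily_mean": means,
            "daily_max": maxes,
        }
    )


class TestDailyToMonthly:
    def test_constant_series(self):
        out = daily_to_monthly(daily_frame([4.0] * 30, [4.0] * 30))
        assert out["mean_t"].iloc[0] == 4.0
        assert out["max_t"].iloc[0] == 4.0

    def test_monthly_mean_of_daily_summaries(self):
        means = np.arange(1.0, 31.0)
        out = daily_to_monthly(daily_frame(means, [40.0] * 30))
        assert out["mean_t"].iloc[0] == pytest.approx(15.5)
        # max_t is the monthly MEAN of daily maxima
        assert out["max_t"].iloc[0] == pytest.approx(40.0)

    def test_max_t_dominates_mean_t(self, default_study):
        monthly = daily_to_monthly(default_study.daily)
        assert (monthly["max_t"] >= monthly["mean_t"] - 1e-12).all()

    def test_inconsistent_daily_summaries_error(self):
        with pytest.raises(ValueError):
            daily_to_monthly(daily_frame([5.0], [4.0]))


class TestSpatialAggregate:
    def monthly(self, cells, values):
        return pd.DataFrame(
            {
                "cell_id": cells,
                "pollutant": "NO2",
                "month_index": 1,
                "calendar_month": 1,
                "mean_t": values,
                "max_t": values,
            }
        )

    def test_mean_and_max_over_cells(self):
        cm = self.monthly(["c1", "c2"], [10.0, 20.0])
        amap = pd.DataFrame({"cell_id": ["c1", "c2"], "area_id": "A"})
        assert spatial_aggregate(cm, amap, "mean")["mean_t"].iloc[0] == 15.0
        assert spatial_aggregate(cm, amap, "max")["mean_t"].iloc[0] == 20.0

    def test_single_cell_area_modes_coincide(self):
        cm = self.monthly(["c1"], [8.5])
        amap = pd.DataFrame({"cell_id": ["c1"], "area_id": "A"})
        assert (
            spatial_aggregate(cm, amap, "mean")["mean_t"].iloc[0]
            == spatial_aggregate(cm, amap, "max")["mean_t"].iloc[0]
        )

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 50, size=5)
        cm = self.monthly([f"c{i}" for i in range(5)], vals)
        amap = pd.DataFrame({"cell_id": [f"c{i}" for i in range(5)], "area_id": "A"})
        assert spatial_aggregate(cm, amap, "mean")["mean_t"].iloc[0] == pytest.approx(
            sum(vals) / 5
        )
        assert spatial_aggregate(cm, amap, "max")["mean_t"].iloc[0] == pytest.approx(
            max(vals)
        )

    def test_unmapped_cells_dropped_but_empty_area_is_error(self):
        cm = self.monthly(["c1", "c2"], [1.0, 2.0])
        amap = pd.DataFrame({"cell_id": ["c1"], "area_id": ["A"]})
        out = spatial_aggregate(cm, amap, "mean")
        assert out["mean_t"].iloc[0] == 1.0  # c2 silently dropped
        amap_bad = pd.DataFrame({"cell_id": ["c1", "zz"], "area_id": ["A", "B"]})
        with pytest.raises(ValueError, match="B"):
            spatial_aggregate(cm, amap_bad, "mean")


class TestFourMetrics:
    def test_ordering_invariants(self, default_study):
        wide = default_study.metrics.pivot_table(
            index=["area_id", "month_index"], columns="metric_name", values="value"
        )
        eps = 1e-9
        assert (wide["max_s.max_t"] >= wide["max_s.mean_t"] - eps).all()
        assert (wide["max_s.max_t"] >= wide["mean_s.max_t"] - eps).all()
        assert (wide["max_s.mean_t"] >= wide["mean_s.mean_t"] - eps).all()
        assert (wide["mean_s.max_t"] >= wide["mean_s.mean_t"] - eps).all()

    def test_permutation_invariance_in_cells_and_days(self):
        rng = np.random.default_rng(1)
        dates = pd.date_range("2007-01-01", periods=10, freq="D")
        rows = []
        for c in ("c1", "c2"):
            dm = rng.uniform(5, 30, size=10)
            for d, v in zip(dates, dm):
                rows.append((c, "NO2", d, v, v + 1.0))
        daily = pd.DataFrame(
            rows, columns=["cell_id", "pollutant", "date", "daily_mean", "daily_max"]
        )
        amap = pd.DataFrame({"cell_id": ["c1", "c2"], "area_id": "A"})
        base = aggregate_metrics(daily, amap)
        shuffled = aggregate_metrics(
            daily.sample(frac=1.0, random_state=9).reset_index(drop=True), amap
        )
        pd.testing.assert_frame_equal(base, shuffled)

    def test_all_cells_equal_every_day_metrics_coincide(self):
        dates = pd.date_range("2007-01-01", periods=8, freq="D")
        rows = [
            (c, "NO2", d, 12.0, 12.0) for c in ("c1", "c2", "c3") for d in dates
        ]
        daily = pd.DataFrame(
            rows, columns=["cell_id", "pollutant", "date", "daily_mean", "daily_max"]
        )
        amap = pd.DataFrame({"cell_id": ["c1", "c2", "c3"], "area_id": "A"})
        out = aggregate_metrics(daily, amap)
        assert set(out["metric_name"]) == set(METRICS)
        assert np.allclose(out["value"], 12.0)


class TestStandardize:
    def test_population_sd_two_points(self):
        z, sd = standardize_metric([0.0, 2.0])
        assert sd == 1.0  # ddof = 0
        assert np.allclose(z, [-1.0, 1.0])

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        z0, _ = standardize_metric(x)
        z1, _ = standardize_metric(a * x + b)
        assert np.allclose(z0, z1, atol=1e-8)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            standardize_metric([3.0, 3.0, 3.0])

    def test_generator_calibrated_to_reference_sd(self):
        # mean_s.mean_t panel calibrated to SD 9.56 within 2% at K*T >= 1000
        from stcar import SyntheticScenario, simulate_study

        study = simulate_study(SyntheticScenario(T=30), seed=1)  # 36 * 30 = 1080 cells
        vals = study.metrics.query(
            "metric_name == 'mean_s.mean_t' and pollutant == 'NO2'"
        )["value"]
        _, sd = standardize_metric(vals)
        assert sd == pytest.approx(9.56, rel=0.02)
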