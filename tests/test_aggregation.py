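import numpy as np
import pandas as pd
import pytest

from keytype.aggregation import (
    aggregate_daily,
    cluster_daily_scores,
    cluster_window_scores,
    daily_event_counts,
    window_aggregate,
)
from keytype.cluster_construction import default_cluster_definitions


def samples_frame(rows):
    df = pd.DataFrame(rows, columns=["subject_id", "date", "feature", "value_s"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def counts_frame(rows):
    df = pd.DataFrame(rows, columns=["subject_id", "date", "day_event_count"])
    df["date"] = pd.to_datetime(df["date"])
    return df


DAY = "2020-01-10"


class TestAggregateDaily:
    def test_mean_median_average(self):
        s = samples_frame([("S1", DAY, "PPL", v) for v in (0.2, 0.2, 0.8)])
        c = counts_frame([("S1", DAY, 100)])
        out = aggregate_daily(s, c, min_events=50)
        assert len(out) == 1
        assert out["daily_value"].iloc[0] == pytest.approx(0.3)
        assert out["n_samples"].iloc[0] == 3

    def test_symmetric_samples_equal_mean(self):
        s = samples_frame([("S1", DAY, "HT", v) for v in (0.1, 0.2, 0.3)])
        c = counts_frame([("S1", DAY, 60)])
        out = aggregate_daily(s, c, min_events=50)
        assert out["daily_value"].iloc[0] == pytest.approx(0.2)

    def test_day_below_event_threshold_excluded(self):
        s = samples_frame(
            [("S1", DAY, "PPL", 0.4), ("S1", "2020-01-11", "PPL", 0.5)]
        )
        c = counts_frame([("S1", DAY, 49), ("S1", "2020-01-11", 50)])
        out = aggregate_daily(s, c, min_events=50)
        assert list(pd.to_datetime(out["date"]).dt.day) == [11]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            aggregate_daily(samples_frame([]), counts_frame([]), min_events=0)

    def test_daily_value_within_sample_range(self, rng):
        vals = rng.lognormal(-1, 0.5, size=25)
        s = samples_frame([("S1", DAY, "PPL", v) for v in vals])
        c = counts_frame([("S1", DAY, 999)])
        out = aggregate_daily(s, c)
        assert vals.min() <= out["daily_value"].iloc[0] <= vals.max()

    def test_permutation_invariance(self, rng):
        vals = list(rng.normal(0.5, 0.1, size=11))
        c = counts_frame([("S1", DAY, 100)])
        a = aggregate_daily(samples_frame([("S1", DAY, "FT", v) for v in vals]), c)
        perm = [vals[i] for i in rng.permutation(len(vals))]
        b = aggregate_daily(samples_frame([("S1", DAY, "FT", v) for v in perm]), c)
        assert a["daily_value"].iloc[0] == pytest.approx(b["daily_value"].iloc[0])


class TestClusterDailyScores:
    def test_mean_of_member_features(self):
        daily = pd.DataFrame(
            {
                "subject_id": "S1",
                "date": pd.to_datetime([DAY] * 3),
                "feature": ["PPL", "RRL", "FT"],
                "n_samples": 5,
                "daily_value": [0.40, 0.44, 0.18],
            }
        )
        out = cluster_daily_scores(daily, ("PPL", "RRL", "FT"))
        assert out["daily_value"].iloc[0] == pytest.approx(0.34)

    def test_single_member_present(self):
        daily = pd.DataFrame(
            {"subject_id": ["S1"], "date": pd.to_datetime([DAY]),
             "feature": ["RRL"], "n_samples": [5], "daily_value": [0.37]}
        )
        out = cluster_daily_scores(daily, ("PPL", "RRL", "FT"))
        assert out["daily_value"].iloc[0] == pytest.approx(0.37)

    def test_no_member_emits_nothing(self):
        daily = pd.DataFrame(
            {"subject_id": ["S1"], "date": pd.to_datetime([DAY]),
             "feature": ["HT"], "n_samples": [5], "daily_value": [0.08]}
        )
        assert cluster_daily_scores(daily, ("PPL", "RRL", "FT")).empty


class TestWindowAggregate:
    @staticmethod
    def visits(date="2020-01-15"):
        return pd.DataFrame(
            {"subject_id": ["S1"], "visit_label": ["M0"], "visit_date": [date]}
        )

    def test_mean_and_day_count(self):
        dc = pd.DataFrame(
            {"subject_id": "S1", "date": pd.to_datetime(["2020-01-10", "2020-01-20"]),
             "daily_value": [0.4, 0.5]}
        )
        out = window_aggregate(dc, self.visits(), "FMSC", 14)
        assert out["value_s"].iloc[0] == pytest.approx(0.45)
        assert out["n_days"].iloc[0] == 2

    def test_no_valid_day_yields_missing(self):
        dc = pd.DataFrame(
            {"subject_id": ["S1"], "date": pd.to_datetime(["2020-03-01"]),
             "daily_value": [0.4]}
        )
        assert window_aggregate(dc, self.visits(), "FMSC", 14).empty

    def test_window_inclusive_at_boundary(self):
        dc = pd.DataFrame(
            {"subject_id": "S1",
             "date": pd.to_datetime(["2020-01-01", "2020-01-29", "2020-01-30"]),
             "daily_value": [0.3, 0.5, 99.0]}
        )
        out = window_aggregate(dc, self.visits(), "FMSC", 14)
        assert out["n_days"].iloc[0] == 2  # ±14 inclusive; the 30th is outside
        assert out["value_s"].iloc[0] == pytest.approx(0.4)

    def test_monotone_containment(self, rng):
        days = pd.to_datetime("2020-01-01") + pd.to_timedelta(
            sorted(rng.choice(60, size=30, replace=False)), unit="D"
        )
        dc = pd.DataFrame(
            {"subject_id": "S1", "date": days, "daily_value": rng.normal(1, 0.1, 30)}
        )
        v = self.visits("2020-01-25")
        n7 = window_aggregate(dc, v, "CSC", 7)["n_days"].iloc[0]
        n14 = window_aggregate(dc, v, "CSC", 14)["n_days"].iloc[0]
        assert n14 >= n7

    def test_score_within_contributing_day_bounds(self, rng):
        days = pd.to_datetime("2020-01-10") + pd.to_timedelta(np.arange(10), unit="D")
        vals = rng.lognormal(0, 0.3, 10)
        dc = pd.DataFrame({"subject_id": "S1", "date": days, "daily_value": vals})
        out = window_aggregate(dc, self.visits(), "CSC", 7)
        lag = (days - pd.Timestamp("2020-01-15")).days
        in_window = vals[np.abs(np.asarray(lag)) <= 7]
        assert in_window.min() <= out["value_s"].iloc[0] <= in_window.max()


class TestAggregationOrders:
    def test_orders_agree_with_equal_coverage(self):
        daily = pd.DataFrame(
            {
                "subject_id": "S1",
                "date": pd.to_datetime([DAY, DAY, "2020-01-11", "2020-01-11"]),
                "feature": ["preCS", "postCS", "preCS", "postCS"],
                "n_samples": 4,
                "daily_value": [0.8, 1.0, 0.9, 1.1],
            }
        )
        visits = pd.DataFrame(
            {"subject_id": ["S1"], "visit_label": ["M0"], "visit_date": ["2020-01-10"]}
        )
        defs = {
            "CSC": type(
                "D", (), {"member_features": ("preCS", "postCS"), "window_half_width_days": 7}
            )
        }
        a = cluster_window_scores(daily, visits, defs, order="days_first")
        b = cluster_window_scores(daily, visits, defs, order="features_first")
        assert a["value_s"].iloc[0] == pytest.approx(b["value_s"].iloc[0])

    def test_orders_differ_with_unequal_coverage(self):
        daily = pd.DataFrame(
            {
                "subject_id": "S1",
                "date": pd.to_datetime([DAY, DAY, "2020-01-11"]),
                "feature": ["preCS", "postCS", "preCS"],
                "n_samples": 4,
                "daily_value": [0.8, 2.0, 1.0],
            }
        )
        visits = pd.DataFrame(
            {"subject_id": ["S1"], "visit_label": ["M0"], "visit_date": ["2020-01-10"]}
        )
        defs = {
            "CSC": type(
                "D", (), {"member_features": ("preCS", "postCS"), "window_half_width_days": 7}
            )
        }
        a = cluster_window_scores(daily, visits, defs, order="days_first")["value_s"].iloc[0]
        b = cluster_window_scores(daily, visits, defs, order="features_first")["value_s"].iloc[0]
        # days_first: mean(day1=(0.8+2.0)/2, day2=1.0) = 1.2; features_first: mean(0.9, 2.0)
        assert a == pytest.approx(1.2)
        assert b == pytest.approx(1.45)

    def test_unknown_order_rejected(self):
        with pytest.raises(ValueError):
            cluster_window_scores(
                pd.DataFrame(columns=["subject_id", "date", "feature", "daily_value"]),
                pd.DataFrame(columns=["subject_id", "visit_label", "visit_date"]),
                default_cluster_definitions(),
                order="bogus",
            )


class TestDailyEventCounts:
    def test_counts_by_utc_day(self):
        day_ms = 86_400_000
        ev = pd.DataFrame(
            {
                "subject_id": ["S1"] * 3 + ["S2"],
                "timestamp_ms": [10, 20, day_ms + 5, 50],
                "action": "press",
                "key_class": "alphanumeric",
                "key_token": "",
            }
        )
        out = daily_event_counts(ev)
        assert len(out) == 3
        s1 = out[out["subject_id"] == "S1"].sort_values("date")
        assert list(s1["day_event_count"]) == [2, 1]
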