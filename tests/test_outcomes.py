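"""Record filtering, daily aggregation and space-time stratum assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tempmort as tm
from tempmort.exposure import ValidationError
from tempmort.outcomes import recode_race


class TestIncludeNonaccidental:
    @pytest.mark.parametrize(
        "code,expected",
        [("A01", True), ("I21", True), ("R99", True), ("S20", False), ("V02", False),
         ("a00", True), ("Z99", False)],
    )
    def test_chapter_rule(self, code, expected):
        assert tm.include_nonaccidental(code) is expected

    def test_prefix_only(self):
        # chapter range acts on the first character; code length is free
        assert tm.include_nonaccidental("R991")
        assert not tm.include_nonaccidental("X599")

    @pytest.mark.parametrize("bad", ["", "9A1", 42, None])
    def test_malformed(self, bad):
        with pytest.raises(ValidationError):
            tm.include_nonaccidental(bad)


class TestFilterRecords:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["municipality_id", "date", "icd10"])

    def test_exclusion_reasons_logged(self):
        df = self._frame(
            [
                ("m1", "2010-01-01", "A41"),
                ("m1", None, "I21"),
                ("m1", "2010-01-03", "V02"),
                ("m2", "2010-01-04", "J18"),
                ("m2", "2010-01-05", "C34"),
            ]
        )
        kept, log = tm.filter_records(df)
        assert len(kept) == 3
        assert log.to_dict() == {"missing_date": 1, "external_cause": 1}

    def test_all_valid_identity(self):
        df = self._frame([("m1", "2010-01-01", "A41"), ("m2", "2010-01-02", "R99")])
        kept, log = tm.filter_records(df)
        assert len(kept) == 2 and log.empty

    def test_empty_input(self):
        kept, log = tm.filter_records(self._frame([]))
        assert kept.empty and log.empty

    def test_invalid_date_and_municipality(self):
        df = self._frame(
            [("", "2010-01-01", "A41"), ("m1", "2010-13-40", "A41"), ("m1", "2010-01-01", "")]
        )
        kept, log = tm.filter_records(df)
        assert kept.empty
        assert log.to_dict() == {
            "missing_municipality": 1,
            "invalid_date": 1,
            "invalid_icd10": 1,
        }

    def test_conservation(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "municipality_id": rng.choice(["m1", "m2", ""], n),
                "date": rng.choice(["2010-01-01", "2010-02-03", None], n),
                "icd10": rng.choice(["A41", "I21", "V02", "Z00"], n),
            }
        )
        kept, log = tm.filter_records(df)
        assert len(kept) + log.sum() == n


class TestRecodeRace:
    def test_parda_joins_black_others_excluded(self):
        df = pd.DataFrame({"race": ["White", "Parda", "Black", "Indigenous", "Asian", None]})
        out, n_excluded = recode_race(df)
        assert list(out["race"][:3]) == ["White", "Black", "Black"]
        assert out["race"][3:5].isna().all()
        assert n_excluded == 2


class TestAggregateCounts:
    def test_zero_filled_counting(self):
        df = pd.DataFrame(
            {
                "municipality_id": ["X"] * 4,
                "date": pd.to_datetime(["2010-01-04"] * 3 + ["2010-01-05"]),
                "icd10": "I21",
            }
        )
        series, _ = tm.aggregate_counts(df, ("2010-01-01", "2010-01-31"))
        (s,) = series
        assert len(s) == 31
        assert s.counts[3] == 3 and s.counts[4] == 1 and s.counts[5] == 0
        assert s.total == 4

    def test_complete_case_subgrouping(self):
        df = pd.DataFrame(
            {
                "municipality_id": ["X"] * 3,
                "date": pd.to_datetime(["2010-01-04"] * 3),
                "sex": ["men", "women", None],
            }
        )
        series, n_incomplete = tm.aggregate_counts(
            df, ("2010-01-01", "2010-01-10"), subgroup_by="sex"
        )
        assert n_incomplete == 1
        assert {s.subgroup for s in series} == {"sex=men", "sex=women"}
        assert sum(s.total for s in series) == 2

    def test_totals_conserved_across_municipalities(self, rng):
        n = 150
        df = pd.DataFrame(
            {
                "municipality_id": rng.choice(["a", "b"], n),
                "date": pd.to_datetime("2010-01-01")
                + pd.to_timedelta(rng.integers(0, 60, n), unit="D"),
            }
        )
        series, _ = tm.aggregate_counts(df, ("2010-01-01", "2010-03-01"))
        assert sum(s.total for s in series) == n

    def test_subgroup_daily_sum_bounded_by_overall(self, rng):
        n = 120
        df = pd.DataFrame(
            {
                "municipality_id": "a",
                "date": pd.to_datetime("2010-01-01")
                + pd.to_timedelta(rng.integers(0, 30, n), unit="D"),
                "sex": rng.choice(["men", "women", None], n, p=[0.45, 0.45, 0.1]),
            }
        )
        window = ("2010-01-01", "2010-01-31")
        (overall,), _ = tm.aggregate_counts(df, window)
        subs, n_miss = tm.aggregate_counts(df, window, subgroup_by="sex")
        daily_sum = np.sum([s.counts for s in subs], axis=0)
        assert np.all(daily_sum <= overall.counts)
        assert daily_sum.sum() + n_miss == overall.total

    def test_window_must_cover_records(self):
        df = pd.DataFrame(
            {"municipality_id": ["X"], "date": pd.to_datetime(["2010-02-05"])}
        )
        with pytest.raises(ValidationError, match="window"):
            tm.aggregate_counts(df, ("2010-01-01", "2010-01-31"))

    def test_missing_modifier_column(self):
        df = pd.DataFrame(
            {"municipality_id": ["X"], "date": pd.to_datetime(["2010-01-05"])}
        )
        with pytest.raises(ValidationError, match="race"):
            tm.aggregate_counts(df, ("2010-01-01", "2010-01-31"), subgroup_by="race")


class TestAssignStrata:
    def test_same_weekday_same_month_share_stratum(self):
        # calendar oracle: 2010-01-04/11/18/25 are all Mondays of Jan 2010
        mondays = pd.DatetimeIndex(
            ["2010-01-04", "2010-01-11", "2010-01-18", "2010-01-25"]
        )
        assert all(d.weekday() == 0 for d in mondays)
        labels = tm.assign_strata(mondays, "X")
        assert labels.nunique() == 1

    def test_month_and_weekday_split_strata(self):
        a = tm.assign_strata(pd.DatetimeIndex(["2010-01-04"]), "X").iloc[0]
        b = tm.assign_strata(pd.DatetimeIndex(["2010-02-01"]), "X").iloc[0]
        c = tm.assign_strata(pd.DatetimeIndex(["2010-01-05"]), "X").iloc[0]
        assert a != b and a != c

    def test_municipality_splits_strata(self):
        d = pd.DatetimeIndex(["2010-01-04"])
        assert (
            tm.assign_strata(d, "X").iloc[0] != tm.assign_strata(d, "Y").iloc[0]
        )

    @given(st.integers(0, 3650))
    @settings(max_examples=60, derandomize=True)
    def test_stratum_members_are_weekday_translates(self, offset):
        # within any stratum, dates share the weekday and differ by multiples of 7
        start = pd.Timestamp("2008-01-01") + pd.Timedelta(days=offset)
        dates = pd.date_range(start, periods=366, freq="D")
        labels = tm.assign_strata(dates, "m")
        for _, grp in pd.Series(dates, index=dates).groupby(labels.values):
            days = grp.dt.dayofweek.unique()
            assert len(days) == 1
            deltas = np.diff(grp.values.astype("datetime64[D]").astype(int))
            assert np.all(deltas % 7 == 0)
            assert 1 <= len(grp) <= 5

    def test_count_table_roundtrip(self, tmp_path):
        dates = pd.date_range("2010-01-01", periods=10)
        s = tm.DeathCountSeries("m1", "all", dates, np.arange(10))
        path = tmp_path / "counts.csv"
        tm.write_count_table([s], path)
        back = pd.read_csv(path)
        assert list(back.columns) == [
            "municipality_id", "subgroup", "date", "count", "stratum_id",
        ]
        assert back["count"].sum() == 45
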