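"""Capture records: growth rates, age classes, seasons, interval extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lizardgrowth import (
    InvalidIntervalError,
    SchemaError,
    assign_age_class,
    assign_season,
    extract_interval,
    extract_intervals,
    growth_rate,
    read_captures,
    read_intervals,
    write_captures,
    write_intervals,
)

from .conftest import capture_table


class TestGrowthRate:
    @pytest.mark.parametrize(
        "l1,l2,days,expected",
        [
            (25.0, 28.0, 60, 0.05),
            (30.0, 30.0, 45, 0.0),
            (33.0, 32.5, 50, -0.01),
        ],
    )
    def test_arithmetic(self, l1, l2, days, expected):
        assert growth_rate(l1, l2, days) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_days_rejected(self):
        with pytest.raises(InvalidIntervalError):
            growth_rate(25.0, 28.0, 0)
        with pytest.raises(InvalidIntervalError):
            growth_rate(25.0, 28.0, -5)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InvalidIntervalError):
            growth_rate(0.0, 28.0, 30)


class TestAgeClass:
    @pytest.mark.parametrize(
        "svl,sex,expected",
        [
            (30.0, "male", "juvenile"),
            (36.0, "female", "adult"),
            (31.5, "male", "juvenile"),  # boundary gap resolves to juvenile
            (32.0, "male", "juvenile"),  # adults are strictly above the threshold
            (32.1, "male", "adult"),
            (35.0, "female", "juvenile"),
            (22.0, "female", "juvenile"),  # hatchling-sized
        ],
    )
    def test_classification(self, svl, sex, expected):
        assert assign_age_class(svl, sex) == expected

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            assign_age_class(30.0, "unknown")


class TestSeason:
    @pytest.mark.parametrize(
        "date,expected",
        [("1989-08-15", "wet"), ("1989-03-10", "dry"), ("1989-12-01", "dry"), ("1989-07-01", "wet")],
    )
    def test_examples(self, date, expected):
        assert assign_season(date) == expected

    def test_year_partitions_into_5_wet_7_dry(self):
        seasons = [assign_season(f"1989-{m:02d}-15") for m in range(1, 13)]
        assert seasons.count("wet") == 5
        assert seasons.count("dry") == 7


class TestExtraction:
    def test_two_captures_sixty_days(self):
        hist = capture_table(
            [("a", "male", "1989-02-01", 25.0), ("a", "male", "1989-04-02", 28.0)]
        )
        iv = extract_interval(hist)
        assert iv.days == 60
        assert iv.gr == pytest.approx(0.05)
        assert iv.l_ref == pytest.approx(26.5)
        assert iv.age_class == "juvenile"
        assert iv.season == "dry"
        assert iv.year == 1989

    def test_single_capture_yields_none(self):
        hist = capture_table([("a", "male", "1989-02-01", 25.0)])
        assert extract_interval(hist) is None

    def test_below_window_floor_yields_none(self):
        hist = capture_table(
            [("a", "male", "1989-02-01", 25.0), ("a", "male", "1989-02-21", 26.0)]
        )
        assert extract_interval(hist) is None

    def test_above_window_ceiling_yields_none(self):
        hist = capture_table(
            [("a", "male", "1989-02-01", 25.0), ("a", "male", "1989-08-01", 35.0)]
        )
        assert extract_interval(hist) is None

    def test_l_ref_first_capture_mode(self):
        hist = capture_table(
            [("a", "male", "1989-02-01", 25.0), ("a", "male", "1989-04-02", 28.0)]
        )
        assert extract_interval(hist, l_ref="l1").l_ref == 25.0

    def test_one_interval_per_individual(self):
        rows = []
        for ind in ("a", "b", "c"):
            rows += [
                (ind, "female", "1989-02-01", 26.0),
                (ind, "female", "1989-03-05", 27.0),
                (ind, "female", "1989-04-02", 28.0),
            ]
        table = extract_intervals(capture_table(rows))
        assert len(table) == 3
        assert table["id"].is_unique
        # first-to-last span, not consecutive pairs
        assert (table["days"] == 60).all()

    def test_per_pair_mode(self):
        rows = [
            ("a", "female", "1989-02-01", 26.0),
            ("a", "female", "1989-03-05", 27.0),
            ("a", "female", "1989-04-05", 28.0),
        ]
        table = extract_intervals(capture_table(rows), per_pair=True)
        assert len(table) == 2  # 32- and 31-day consecutive pairs

    def test_shrinkage_flagged_and_excludable(self):
        rows = [
            ("a", "female", "1989-02-01", 28.0),
            ("a", "female", "1989-04-02", 27.0),
        ]
        table = extract_intervals(capture_table(rows))
        assert bool(table["shrinkage"].iloc[0])
        assert extract_intervals(capture_table(rows), drop_shrinkage=True).empty

    def test_conflicting_sex_rejected(self):
        rows = [
            ("a", "female", "1989-02-01", 26.0),
            ("a", "male", "1989-04-02", 28.0),
        ]
        with pytest.raises(SchemaError):
            extract_intervals(capture_table(rows))

    @settings(deadline=None, max_examples=50)
    @given(
        l1=st.floats(min_value=20.0, max_value=50.0),
        l2=st.floats(min_value=20.0, max_value=50.0),
        days=st.integers(min_value=30, max_value=100),
    )
    def test_stored_rate_consistent_with_endpoints(self, l1, l2, days):
        start = pd.Timestamp("1989-03-01")
        hist = capture_table(
            [("x", "female", start, l1), ("x", "female", start + pd.Timedelta(days=days), l2)]
        )
        iv = extract_interval(hist)
        assert iv.gr == pytest.approx((iv.l2 - iv.l1) / iv.days, abs=1e-12)
        assert min(l1, l2) <= iv.l_ref <= max(l1, l2)


class TestRoundTrip:
    def test_captures_roundtrip_reproduces_intervals(self, tmp_path, rng):
        rows = []
        start = pd.Timestamp("1989-01-10")
        for i in range(25):
            sex = "male" if i % 2 else "female"
            t0 = start + pd.Timedelta(days=int(rng.integers(0, 200)))
            days = int(rng.integers(30, 101))
            l1 = float(rng.uniform(23, 40))
            l2 = l1 + float(rng.uniform(-0.5, 4.0))
            rows += [(f"i{i}", sex, t0, round(l1, 2)), (f"i{i}", sex, t0 + pd.Timedelta(days=days), round(l2, 2))]
        captures = capture_table(rows)
        before = extract_intervals(captures)

        path = tmp_path / "captures.csv"
        write_captures(captures, path)
        after = extract_intervals(read_captures(path))
        pd.testing.assert_frame_equal(
            before.drop(columns=["date_first", "mid_date"]),
            after.drop(columns=["date_first", "mid_date"]),
        )

    def test_interval_csv_roundtrip(self, tmp_path):
        rows = [
            ("a", "female", "1989-02-01", 26.0),
            ("a", "female", "1989-04-02", 28.0),
        ]
        table = extract_intervals(capture_table(rows))
        path = tmp_path / "intervals.csv"
        write_intervals(table, path)
        back = read_intervals(path)
        assert back["gr_mm_per_day"].iloc[0] == pytest.approx(table["gr_mm_per_day"].iloc[0])

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"id": ["a"], "date": ["1989-01-01"], "svl_mm": [25.0]}).to_csv(path, index=False)
        with pytest.raises(SchemaError):
            read_captures(path)

    def test_out_of_bounds_svl_flagged(self, tmp_path):
        path = tmp_path / "captures.csv"
        pd.DataFrame(
            {
                "id": ["a", "b"],
                "sex": ["male", "male"],
                "date": ["1989-01-01", "1989-01-02"],
                "svl_mm": [25.0, 150.0],
                "mass_g": [np.nan, np.nan],
            }
        ).to_csv(path, index=False)
        frame = read_captures(path)
        assert frame["valid"].tolist() == [True, False]
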