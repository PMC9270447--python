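"""Loading, validation, windowing and daily summaries of timestamped data."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agebench import (
    ScenarioConfig,
    TimeWindow,
    generate_scenario,
    load_timestamped_table,
    slice_window,
    summarize_timeline,
    validate_dataset,
)
from agebench.timeline import (
    EmptyWindowError,
    FeatureTypeError,
    MissingDataError,
    SchemaError,
    TimestampFormatError,
)

from conftest import make_dataset


def _write(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoad:
    def test_day_offsets_from_first_record(self, tmp_path):
        p = _write(tmp_path, "timestamp,x1,target\n2020-01-01,1.0,10\n2020-01-02,2.0,11\n2020-01-03,3.0,12\n")
        ds = load_timestamped_table(p, "timestamp", "target")
        assert ds.n_records == 3
        np.testing.assert_allclose(ds.timestamps, [0.0, 1.0, 2.0])
        assert ds.feature_names == ["x1"]

    def test_shuffled_rows_sorted_on_load(self, tmp_path):
        a = _write(tmp_path, "timestamp,x1,target\n2020-01-01,1.0,10\n2020-01-02,2.0,11\n2020-01-03,3.0,12\n", "a.csv")
        b = _write(tmp_path, "timestamp,x1,target\n2020-01-03,3.0,12\n2020-01-01,1.0,10\n2020-01-02,2.0,11\n", "b.csv")
        da, db = (load_timestamped_table(p, "timestamp", "target") for p in (a, b))
        np.testing.assert_array_equal(da.timestamps, db.timestamps)
        np.testing.assert_array_equal(da.features, db.features)
        np.testing.assert_array_equal(da.target, db.target)

    def test_empty_target_cell_names_row_and_column(self, tmp_path):
        p = _write(tmp_path, "timestamp,x1,target\n2020-01-01,1.0,10\n2020-01-02,2.0,\n")
        with pytest.raises(MissingDataError, match=r"row 3.*target"):
            load_timestamped_table(p, "timestamp", "target", feature_columns=["x1"])

    def test_bad_timestamp_names_row(self, tmp_path):
        p = _write(tmp_path, "timestamp,x1,target\n2020-01-01,1.0,10\nnot-a-date,2.0,11\n")
        with pytest.raises(TimestampFormatError, match="row 3"):
            load_timestamped_table(p, "timestamp", "target")

    def test_non_numeric_feature_cell(self, tmp_path):
        p = _write(tmp_path, "timestamp,x1,target\n2020-01-01,abc,10\n2020-01-02,2.0,11\n")
        with pytest.raises(FeatureTypeError, match="x1"):
            load_timestamped_table(p, "timestamp", "target", feature_columns=["x1"])

    def test_duplicate_columns_rejected(self, tmp_path):
        p = _write(tmp_path, "timestamp,x1,x1,target\n2020-01-01,1,2,10\n")
        with pytest.raises(SchemaError, match="duplicate"):
            load_timestamped_table(p, "timestamp", "target")

    def test_sub_day_resolution_kept_fractional(self, tmp_path):
        p = _write(tmp_path, "timestamp,x1,target\n2020-01-01T00:00:00,1,10\n2020-01-01T12:00:00,2,11\n2020-01-03T06:00:00,1,9\n")
        ds = load_timestamped_table(p, "timestamp", "target")
        np.testing.assert_allclose(ds.timestamps, [0.0, 0.5, 2.25])


class TestSliceWindow:
    def test_half_open_convention(self):
        ds = make_dataset([0.0, 1.0, 2.0, 3.0])
        sub = slice_window(ds, TimeWindow(1.0, 3.0))
        np.testing.assert_array_equal(sub.timestamps, [1.0, 2.0])

    def test_full_span_round_trip(self):
        ds = make_dataset([0.0, 1.0, 2.0, 3.0])
        sub = slice_window(ds, TimeWindow(0.0, ds.span + 1.0))
        np.testing.assert_array_equal(sub.timestamps, ds.timestamps)
        np.testing.assert_array_equal(sub.features, ds.features)

    def test_empty_window_error_names_window(self):
        ds = make_dataset([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(EmptyWindowError, match=r"\[10.0, 11.0\)"):
            slice_window(ds, TimeWindow(10.0, 11.0))

    @given(split=st.floats(min_value=0.5, max_value=9.5))
    @settings(max_examples=25, deadline=None)
    def test_adjacent_windows_partition_records(self, split):
        ds = make_dataset(np.linspace(0, 10, 40))
        left = ds.window_record_count(TimeWindow(0.0, split))
        right = ds.window_record_count(TimeWindow(split, 10.0 + 1e-9))
        assert left + right == ds.n_records


class TestSummarize:
    def test_constant_target(self):
        ds = make_dataset(np.arange(100.0), target=np.full(100, 5.0))
        s = summarize_timeline(ds, ma_window_days=7)
        np.testing.assert_allclose(s.daily_mean, 5.0)
        np.testing.assert_allclose(s.moving_average, 5.0)

    def test_multiple_records_per_day_averaged(self):
        ds = make_dataset([0.25, 0.75], target=[1.0, 3.0])
        s = summarize_timeline(ds)
        assert s.daily_mean[0] == 2.0
        assert s.daily_count[0] == 2

    def test_moving_average_matches_convolution(self):
        ds = make_dataset(np.arange(10.0), target=np.arange(10.0))
        s = summarize_timeline(ds, ma_window_days=3)
        interior = np.convolve(np.arange(10.0), np.ones(3) / 3, mode="valid")
        np.testing.assert_allclose(s.moving_average[1:-1], interior)


class TestValidate:
    def test_span_gate(self):
        short = make_dataset(np.linspace(0, 365, 400))
        assert not validate_dataset(short, min_span_days=730).passed
        long = make_dataset(np.linspace(0, 1100, 1200))
        assert validate_dataset(long, min_span_days=730).passed

    def test_level_shift_flagged_at_shift_day(self):
        rng = np.random.default_rng(3)
        days = np.arange(300.0)
        target = rng.standard_normal(300)  # daily SD = 1
        target[150:] += 20.0  # one-day level shift of 20 SD
        ds = make_dataset(days, target=target)
        report = validate_dataset(ds, min_span_days=100)
        assert report.abrupt_change_flag
        assert any(abs(t - 150) <= 3 for t in report.abrupt_change_times)

    def test_stationary_scenario_never_flags(self):
        for seed in range(20):
            ds = generate_scenario(ScenarioConfig(kind="stationary", seed=seed))
            report = validate_dataset(ds)
            assert report.passed
            assert not report.abrupt_change_flag, f"false abrupt-change flag at seed {seed}"
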