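import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nocturne import preprocess
from nocturne.data_io import DEFAULT_TZ, RawGlucoseRecord, RawWearableRecord
from nocturne.preprocess import (
    GAP_FILLED,
    INTERPOLATED,
    MEASURED,
    availability_filter,
    dedupe_mean,
    fill_gaps,
    fuse_glucose,
    map_activity_to_met,
    quality_gate,
    to_grid,
    window_mean_resample,
)
from tests.conftest import make_series


def _ts(s):
    return pd.Timestamp(s).tz_localize(DEFAULT_TZ)


def _g(t, v, source="cgm"):
    return RawGlucoseRecord("P01", _ts(t), v, source)


def _w(t, v, q=None, channel="heart_rate"):
    return RawWearableRecord("P01", _ts(t), channel, v, q)


class TestFuseGlucose:
    def test_lower_smbg_overwrites_cgm_in_shared_slot(self):
        fused = fuse_glucose(
            [_g("2023-07-10 10:00", 5.0)],
            [_g("2023-07-10 10:00", 4.5, "smbg")],
        )
        assert [(r.value, r.source) for r in fused] == [(4.5, "smbg")]

    def test_lower_cgm_kept_over_higher_smbg(self):
        fused = fuse_glucose(
            [_g("2023-07-10 10:00", 3.4)],
            [_g("2023-07-10 10:00", 3.8, "smbg")],
        )
        assert [(r.value, r.source) for r in fused] == [(3.4, "cgm")]

    def test_smbg_only_slot_inserted_at_original_timestamp(self):
        fused = fuse_glucose(
            [_g("2023-07-10 10:00", 5.0)],
            [_g("2023-07-10 10:07", 3.5, "smbg")],
        )
        assert [r.timestamp.minute for r in fused] == [0, 7]

    def test_mixed_participants_rejected(self):
        other = RawGlucoseRecord("P02", _ts("2023-07-10 10:00"), 5.0, "cgm")
        with pytest.raises(ValueError, match="mixed participants"):
            fuse_glucose([_g("2023-07-10 10:05", 5.0)], [other])

    def test_order_insensitive(self):
        cgm = [_g("2023-07-10 10:00", 5.0), _g("2023-07-10 10:05", 6.0)]
        smbg = [_g("2023-07-10 10:01", 4.5, "smbg")]
        a = fuse_glucose(cgm, smbg)
        b = fuse_glucose(list(reversed(cgm)), smbg)
        assert a == b


class TestToGrid:
    def test_linear_interpolation_between_records(self):
        series = to_grid(
            [_g("2023-07-10 10:00", 4.0), _g("2023-07-10 10:15", 7.0)]
        )
        assert series.values.iloc[1] == pytest.approx(5.0)
        assert series.values.iloc[2] == pytest.approx(6.0)
        assert list(series.provenance) == [
            MEASURED, INTERPOLATED, INTERPOLATED, MEASURED,
        ]

    def test_record_on_grid_passes_through(self):
        series = to_grid([_g("2023-07-10 10:00", 4.0), _g("2023-07-10 10:05", 5.0)])
        assert series.values.iloc[0] == 4.0
        assert series.provenance.iloc[0] == MEASURED

    def test_15min_native_yields_two_interpolated_per_interval(self):
        records = [
            _g("2023-07-10 10:00", 4.0),
            _g("2023-07-10 10:15", 7.0),
            _g("2023-07-10 10:30", 5.5),
        ]
        series = to_grid(records)
        assert (series.provenance == INTERPOLATED).sum() == 4

    @given(
        v0=st.floats(3.0, 15.0),
        v1=st.floats(3.0, 15.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_interpolated_values_within_bracketing_records(self, v0, v1):
        series = to_grid([_g("2023-07-10 10:00", v0), _g("2023-07-10 10:15", v1)])
        lo, hi = min(v0, v1), max(v0, v1)
        assert ((series.values >= lo - 1e-9) & (series.values <= hi + 1e-9)).all()


class TestFillGaps:
    def test_missing_value_gets_day_mean(self):
        series = make_series([4.0, 6.0, np.nan])
        series.values.iloc[2] = np.nan
        series.provenance.iloc[2] = None
        filled = fill_gaps(series)
        assert filled.values.iloc[2] == pytest.approx(5.0)
        assert filled.provenance.iloc[2] == GAP_FILLED

    def test_no_gaps_is_identity(self):
        series = make_series([4.0, 6.0, 5.0])
        filled = fill_gaps(series)
        assert filled.values.equals(series.values)

    def test_all_missing_day_is_error(self):
        series = make_series([np.nan, np.nan])
        with pytest.raises(ValueError, match="no non-missing"):
            fill_gaps(series)

    def test_idempotent(self):
        series = make_series([4.0, np.nan, 6.0])
        once = fill_gaps(series)
        twice = fill_gaps(once)
        assert twice.values.equals(once.values)


class TestDedupeMean:
    def test_duplicates_replaced_by_mean(self):
        out = dedupe_mean([_w("2023-07-10 10:00", 10), _w("2023-07-10 10:00", 20)])
        assert len(out) == 1 and out[0].value == 15

    def test_three_duplicates(self):
        out = dedupe_mean(
            [
                _w("2023-07-10 10:00", 1),
                _w("2023-07-10 10:00", 2),
                _w("2023-07-10 10:00", 6),
            ]
        )
        assert out[0].value == pytest.approx(3.0)

    def test_no_duplicates_identity_and_idempotent(self):
        records = [_w("2023-07-10 10:00", 1), _w("2023-07-10 10:01", 2)]
        assert dedupe_mean(records) == records
        assert dedupe_mean(dedupe_mean(records)) == dedupe_mean(records)

    def test_order_insensitive(self):
        records = [
            _w("2023-07-10 10:01", 2),
            _w("2023-07-10 10:00", 1),
            _w("2023-07-10 10:00", 3),
        ]
        assert dedupe_mean(records) == dedupe_mean(list(reversed(records)))


class TestQualityGate:
    def test_boundary_is_strictly_less_than(self):
        kept = quality_gate(
            [_w("2023-07-10 10:00", 1, 49.0), _w("2023-07-10 10:01", 2, 50.0)]
        )
        assert [r.quality for r in kept] == [50.0]

    def test_all_below_threshold_empties_list(self):
        assert quality_gate([_w("2023-07-10 10:00", 1, 10.0)]) == []

    def test_channel_without_quality_passes(self):
        records = [_w("2023-07-10 10:00", 1, None)]
        assert quality_gate(records) == records


class TestAvailabilityFilter:
    def test_boundary_30_percent_kept(self):
        records = [_w(f"2023-07-10 10:{m:02d}", 1) for m in range(3)]
        assert availability_filter(records, day_span_s=600, native_step_s=60)

    def test_10_percent_dropped(self):
        records = [_w("2023-07-10 10:00", 1)]
        assert not availability_filter(records, day_span_s=600, native_step_s=60)

    def test_full_coverage_kept(self):
        records = [_w(f"2023-07-10 10:{m:02d}", 1) for m in range(10)]
        assert availability_filter(records, day_span_s=600, native_step_s=60)


class TestWindowMeanResample:
    def test_window_mean(self):
        records = [
            _w("2023-07-10 10:00", 60),
            _w("2023-07-10 10:01", 62),
            _w("2023-07-10 10:04", 64),
        ]
        col = window_mean_resample(records)
        assert col.iloc[0] == pytest.approx(62.0)

    def test_empty_window_missing(self):
        records = [_w("2023-07-10 10:00", 60), _w("2023-07-10 10:11", 64)]
        col = window_mean_resample(records)
        assert np.isnan(col.iloc[1])

    def test_high_rate_window_collapses_to_mean(self):
        records = [
            _w(f"2023-07-10 10:00:{s:02d}", float(s)) for s in range(0, 60, 2)
        ]
        col = window_mean_resample(records)
        assert col.iloc[0] == pytest.approx(np.mean(np.arange(0, 60, 2)))


class TestMetMapping:
    @pytest.mark.parametrize(
        "cls,met",
        [("Running up", 13.0), ("Sleeping", 1.0), ("Biking up", 10.0),
         ("Standing", 2.0)],
    )
    def test_table_lookup(self, cls, met):
        assert map_activity_to_met(cls) == met

    @pytest.mark.parametrize(
        "cls", ["Undefined", "Other", "Ctrl rest med ee",
                "Measured and relevant improvement in Sleep"]
    )
    def test_classes_without_intensity_map_to_missing(self, cls):
        assert map_activity_to_met(cls) is None

    def test_unknown_class_raises_with_vocabulary(self):
        with pytest.raises(KeyError, match="Running up"):
            map_activity_to_met("Moonwalking")

    def test_table_has_27_activities(self):
        assert len(preprocess.MET_TABLE) == 27
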