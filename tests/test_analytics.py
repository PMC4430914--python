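"""Click-stream analytics: parsing, procedures, timing, bootstrap, rates."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from cvdscreen.analytics import (
    ClickEvent,
    ProcedureRecord,
    bluetooth_usage,
    build_procedures,
    convert_glucose,
    dissemination_rates,
    duration_summary,
    glucose_entry_errors,
    likert_summary,
    parse_event_log,
    sequential_bootstrap_ci,
    write_event_log,
)
from cvdscreen.synth import scripted_event_stream

T0 = datetime(2013, 6, 1, 9, 0, 0)


def ts(minutes):
    return T0 + timedelta(minutes=minutes)


def minimal_encounter(enc, user, start_min, dur_min=20.0):
    """A complete 4-step encounter spanning dur_min minutes."""
    events = []
    step_len = dur_min / 4
    for k in (1, 2, 3, 4):
        s = start_min + (k - 1) * step_len
        events.append(ClickEvent(ts(s), user, enc, k, "step_start"))
        events.append(ClickEvent(ts(s + step_len), user, enc, k, "step_complete"))
    return events


class TestParsing:
    def test_well_formed_rows_sorted(self, tmp_path):
        events = [
            ClickEvent(ts(2), "w1", "e1", 1, "step_complete"),
            ClickEvent(ts(0), "w1", "e1", 1, "step_start"),
            ClickEvent(ts(1), "w1", "e1", 1, "bp_start"),
        ]
        path = tmp_path / "log.csv"
        write_event_log(events, path)
        parsed, malformed = parse_event_log(path)
        assert malformed == []
        assert [e.timestamp for e in parsed] == [ts(0), ts(1), ts(2)]

    @pytest.mark.parametrize(
        "row,reason",
        [
            ("not-a-time,w1,e1,1,step_start,", "timestamp"),
            ("2013-06-01T09:00:00,w1,e1,9,step_start,", "step"),
            ("2013-06-01T09:00:00,w1,e1,1,teleport,", "element"),
            ("2013-06-01T09:00:00,w1,e1,4,likert_rating,7", "likert"),
        ],
    )
    def test_malformed_rows_collected_with_line_numbers(self, tmp_path, row, reason):
        path = tmp_path / "log.csv"
        path.write_text(
            "timestamp,user_id,encounter_id,step,element_id,value\n"
            "2013-06-01T09:00:00,w1,e1,1,step_start,\n" + row + "\n",
            encoding="utf-8",
        )
        events, malformed = parse_event_log(path)
        assert len(events) == 1
        assert len(malformed) == 1
        assert malformed[0].line_no == 3
        assert reason in malformed[0].reason

    def test_large_generated_log_round_trips(self, tmp_path):
        events = scripted_event_stream(
            "w1", 200, bluetooth_procedures=range(1, 100),
            section_visits={"risk_meter": range(1, 150)},
        )
        path = tmp_path / "big.csv"
        write_event_log(events, path)
        parsed, malformed = parse_event_log(path)
        assert malformed == []
        assert parsed == sorted(events, key=lambda e: (e.timestamp, e.encounter_id))


class TestBuildProcedures:
    def test_non_overlapping_encounters_are_sequential(self):
        events = minimal_encounter("e1", "w1", 0) + minimal_encounter("e2", "w1", 30)
        procs = build_procedures(sorted(events, key=lambda e: e.timestamp))
        assert [p.sequential for p in procs] == [True, True]
        assert all(p.complete for p in procs)

    def test_interleaved_same_user_both_non_sequential(self):
        events = minimal_encounter("e1", "w1", 0, dur_min=40) + minimal_encounter(
            "e2", "w1", 10, dur_min=10)
        procs = build_procedures(sorted(events, key=lambda e: e.timestamp))
        assert [p.sequential for p in procs] == [False, False]

    def test_overlap_across_users_is_fine(self):
        events = minimal_encounter("e1", "w1", 0, dur_min=40) + minimal_encounter(
            "e2", "w2", 10, dur_min=10)
        procs = build_procedures(sorted(events, key=lambda e: e.timestamp))
        assert all(p.sequential for p in procs)

    def test_missing_step4_completion_flags_incomplete(self):
        events = [e for e in minimal_encounter("e1", "w1", 0)
                  if not (e.step == 4 and e.element_id == "step_complete")]
        procs = build_procedures(events)
        assert not procs[0].complete

    def test_every_event_lands_in_exactly_one_record(self):
        events = sorted(
            minimal_encounter("e1", "w1", 0) + minimal_encounter("e2", "w1", 30)
            + minimal_encounter("e3", "w2", 5),
            key=lambda e: e.timestamp,
        )
        procs = build_procedures(events)
        assert sorted(p.encounter_id for p in procs) == ["e1", "e2", "e3"]

    def test_bluetooth_and_bp_acquisition_span(self):
        events = minimal_encounter("e1", "w1", 0)
        events += [
            ClickEvent(ts(10.0), "w1", "e1", 3, "bp_start"),
            ClickEvent(ts(13.5), "w1", "e1", 3, "bp_bluetooth_receive"),
        ]
        proc = build_procedures(sorted(events, key=lambda e: e.timestamp))[0]
        assert proc.bluetooth_used
        assert proc.bp_acquisition_seconds == pytest.approx(210.0)


class TestDurations:
    def make_procs(self, minutes):
        return [
            ProcedureRecord("e%d" % i, "w1", ts(i * 100), ts(i * 100 + m))
            for i, m in enumerate(minutes)
        ]

    def test_median_and_iqr_by_hand(self):
        summary = duration_summary(self.make_procs([10, 20, 30]))
        assert summary.loc["total", "median_s"] == pytest.approx(20 * 60)
        assert summary.loc["total", "iqr_s"] == pytest.approx(10 * 60)

    def test_single_procedure_iqr_zero(self):
        summary = duration_summary(self.make_procs([25]))
        assert summary.loc["total", "median_s"] == pytest.approx(25 * 60)
        assert summary.loc["total", "iqr_s"] == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            duration_summary([])

    def test_non_sequential_excluded(self):
        procs = self.make_procs([10, 20, 30, 500])
        procs[-1].sequential = False
        assert duration_summary(procs).loc["total", "n"] == 3


class TestSequentialBootstrap:
    def test_constant_series_collapses(self):
        series = sequential_bootstrap_ci([600.0] * 10, n_boot=200, seed=1)
        assert (series["mean_s"] == 600).all()
        assert (series["ci_low_s"] == 600).all()
        assert (series["ci_high_s"] == 600).all()

    def test_k1_collapses_to_single_value(self):
        series = sequential_bootstrap_ci([1234.0, 900.0], n_boot=100, seed=1)
        assert series.loc[1, "ci_low_s"] == series.loc[1, "ci_high_s"] == 1234.0

    def test_seed_reproducible_bit_for_bit(self):
        durations = list(np.random.default_rng(5).normal(1800, 300, 15))
        a = sequential_bootstrap_ci(durations, n_boot=500, seed=42)
        b = sequential_bootstrap_ci(durations, n_boot=500, seed=42)
        assert a.equals(b)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            sequential_bootstrap_ci([1.0, 2.0], n_boot=10)

    def test_interval_ordering_invariant(self):
        durations = list(np.random.default_rng(6).lognormal(7, 0.5, 20))
        series = sequential_bootstrap_ci(durations, n_boot=500, seed=3)
        assert (series["ci_low_s"] <= series["mean_s"]).all()
        assert (series["mean_s"] <= series["ci_high_s"]).all()

    def test_wider_level_widens_every_interval(self):
        durations = list(np.random.default_rng(7).normal(1800, 300, 15))
        narrow = sequential_bootstrap_ci(durations, n_boot=500, level=0.8, seed=9)
        wide = sequential_bootstrap_ci(durations, n_boot=500, level=0.99, seed=9)
        assert (wide["ci_low_s"] <= narrow["ci_low_s"]).all()
        assert (wide["ci_high_s"] >= narrow["ci_high_s"]).all()

    def test_ci_width_shrinks_in_expectation(self):
        rng = np.random.default_rng(11)
        widths_early, widths_late = [], []
        for seed in range(30):
            durations = rng.normal(1800, 300, 20)
            series = sequential_bootstrap_ci(list(durations), n_boot=300, seed=seed)
            width = series["ci_high_s"] - series["ci_low_s"]
            widths_early.append(width.loc[5])
            widths_late.append(width.loc[20])
        assert np.mean(widths_late) < np.mean(widths_early)


class TestRates:
    def test_bluetooth_17_of_28_prints_61(self):
        events = scripted_event_stream("w1", 28, bluetooth_procedures=range(1, 18))
        usage = bluetooth_usage(build_procedures(events))
        assert (usage.n_used, usage.n_procedures) == (17, 28)
        assert usage.rate_percent == 61

    def test_bluetooth_zero(self):
        events = scripted_event_stream("w1", 5)
        usage = bluetooth_usage(build_procedures(events))
        assert usage.rate_percent == 0
        assert usage.mean_acquisition_s is None

    def test_bluetooth_raw_fraction_authoritative(self):
        events = scripted_event_stream("w1", 16, bluetooth_procedures=range(1, 7))
        usage = bluetooth_usage(build_procedures(events))
        assert usage.fraction == pytest.approx(6 / 16)

    def test_bluetooth_before_after_split(self):
        events = scripted_event_stream("w1", 20, bluetooth_procedures=range(10, 21))
        usage = bluetooth_usage(build_procedures(events), split_index=9)
        assert usage.fraction_before == 0.0
        assert usage.fraction_after == 1.0

    def test_dissemination_fractions(self):
        events = scripted_event_stream(
            "w1", 28,
            section_visits={"risk_meter": range(1, 23),
                            "recommendations": range(1, 28),
                            "next_visit": range(1, 27)},
        )
        rates = dissemination_rates(build_procedures(events)).set_index("section")
        assert rates.loc["risk_meter", "percent"] == 79
        assert rates.loc["recommendations", "percent"] == 96
        assert rates.loc["next_visit", "percent"] == 93

    def test_dissemination_zero(self):
        events = scripted_event_stream("w1", 4)
        rates = dissemination_rates(build_procedures(events))
        assert (rates["percent"] == 0).all()


class TestGlucoseErrors:
    def entries(self, values, start=0):
        return [(ts(start + 30 * i), float(v)) for i, v in enumerate(values)]

    def test_identical_lists_no_errors(self):
        entered = self.entries([100, 110, 120])
        report = glucose_entry_errors(entered, entered)
        assert report.n_matched == 3 and report.n_errors == 0

    def test_transposition_error_magnitude(self):
        report = glucose_entry_errors(self.entries([181]), self.entries([118]))
        assert report.n_errors == 1
        assert report.errors == (63.0,)

    def test_out_of_window_reading_unmatched(self):
        entered = [(ts(0), 100.0)]
        meter = [(ts(30), 100.0)]
        report = glucose_entry_errors(entered, meter, tolerance_minutes=10)
        assert report.n_matched == 0
        assert report.unmatched_entered == (ts(0),)

    def test_greedy_matching_prefers_nearest(self):
        entered = [(ts(0), 100.0), (ts(5), 200.0)]
        meter = [(ts(1), 100.0), (ts(4), 200.0)]
        report = glucose_entry_errors(entered, meter)
        assert report.n_matched == 2 and report.n_errors == 0

    def test_matching_symmetric_in_error_magnitudes(self):
        entered = self.entries([181, 95, 142])
        meter = self.entries([118, 95, 140])
        a = glucose_entry_errors(entered, meter)
        b = glucose_entry_errors(meter, entered)
        assert sorted(a.errors) == sorted(b.errors)

    def test_median_iqr_over_nonzero_errors(self):
        entered = self.entries([100, 110, 130, 150])
        meter = self.entries([100, 120, 120, 120])
        report = glucose_entry_errors(entered, meter)
        assert report.n_errors == 3
        assert report.median_error == pytest.approx(10.0)


class TestLikertAndConversion:
    def test_all_top_ratings(self):
        summary = likert_summary([4, 4, 4])
        assert summary.fraction_at_or_above == 1.0
        assert summary.minimum == 4

    def test_threshold_counting(self):
        summary = likert_summary([3, 3, 4, 4], threshold=4)
        assert summary.fraction_at_or_above == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            likert_summary([])

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            likert_summary([3, 5])

    def test_mgdl_to_mmol_reporting(self):
        rounded, raw = convert_glucose(9.55, "mgdl_to_mmol")
        assert rounded == 0.53
        assert raw == pytest.approx(9.55 / 18.016)

    def test_zero_and_negative(self):
        assert convert_glucose(0, "mgdl_to_mmol")[0] == 0
        with pytest.raises(ValueError):
            convert_glucose(-1, "mgdl_to_mmol")

    def test_round_trip_identity_on_raw_path(self):
        for x in (1.0, 9.55, 180.0):
            _, mmol = convert_glucose(x, "mgdl_to_mmol")
            _, back = convert_glucose(mmol, "mmol_to_mgdl")
            assert back == pytest.approx(x, abs=1e-9)
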