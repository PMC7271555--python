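"""Epoch processing: file reading, re-integration, non-wear, summaries."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from actiplan import (
    EpochDayPlan,
    EpochSeries,
    FormatError,
    InvalidConfigError,
    detect_nonwear,
    generate_epoch_day,
    include_subjects,
    process_stream,
    read_epoch_file,
    reintegrate,
    summarize_day,
    write_epoch_stream,
)
from actiplan.cohort import summaries_to_frame
from actiplan.synthetic import BASE_DATE, random_epoch_day_plan

T0 = pd.Timestamp("2020-01-06 08:00:00")


def series_60s(cpm, subject_id="S1", start=T0):
    return EpochSeries(subject_id, start, 60, np.asarray(cpm))


class TestReadEpochFile:
    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text(
            "subject_id,timestamp,counts\n"
            "S1,2020-01-06T08:00:00,10\nS1,2020-01-06T08:00:05,0\nS1,2020-01-06T08:00:10,3\n"
        )
        (s,) = read_epoch_file(p)
        assert len(s) == 3 and s.epoch_s == 5
        np.testing.assert_array_equal(s.counts, [10, 0, 3])

    def test_negative_count_names_row(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text(
            "subject_id,timestamp,counts\n"
            "S1,2020-01-06T08:00:00,10\nS1,2020-01-06T08:00:05,-4\n"
        )
        with pytest.raises(FormatError, match="row 2"):
            read_epoch_file(p)

    @pytest.mark.parametrize("bad_ts", ["2020-01-06T08:00:05", "2020-01-06T08:00:12"])
    def test_duplicate_or_nonuniform_timestamps(self, tmp_path, bad_ts):
        p = tmp_path / "e.csv"
        p.write_text(
            "subject_id,timestamp,counts\n"
            "S1,2020-01-06T08:00:00,1\nS1,2020-01-06T08:00:05,2\n"
            f"S1,{bad_ts},3\n"
        )
        with pytest.raises(FormatError):
            read_epoch_file(p)

    def test_interleaved_subjects_split_and_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        sa = EpochSeries("A", T0, 5, rng.integers(0, 50, 24))
        sb = EpochSeries("B", T0, 5, rng.integers(0, 50, 24))
        p = tmp_path / "e.csv"
        write_epoch_stream([sa, sb], p)
        # interleave rows to check order independence
        df = pd.read_csv(p)
        df = df.sort_values("timestamp", kind="stable")
        df.to_csv(p, index=False)
        out = {s.subject_id: s for s in read_epoch_file(p)}
        assert set(out) == {"A", "B"}
        np.testing.assert_array_equal(out["A"].counts, sa.counts)
        np.testing.assert_array_equal(out["B"].counts, sb.counts)

    def test_tab_delimiter_autodetected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(
            "subject_id\ttimestamp\tcounts\nS1\t2020-01-06T08:00:00\t7\n"
            "S1\t2020-01-06T08:00:05\t8\n"
        )
        (s,) = read_epoch_file(p)
        np.testing.assert_array_equal(s.counts, [7, 8])


class TestReintegrate:
    def test_sums_blocks(self):
        s = EpochSeries("S1", T0, 5, np.full(12, 10))
        out = reintegrate(s, 60)
        np.testing.assert_array_equal(out.counts, [120])
        assert out.epoch_s == 60

    def test_identity_at_same_epoch(self):
        s = series_60s([5, 6])
        assert reintegrate(s, 60) is s

    def test_partial_trailing_block_dropped(self):
        s = EpochSeries("S1", T0, 5, np.ones(25, dtype=int))
        out = reintegrate(s, 60)
        np.testing.assert_array_equal(out.counts, [12, 12])

    def test_idempotent(self):
        s = EpochSeries("S1", T0, 5, np.arange(120))
        once = reintegrate(s, 60)
        np.testing.assert_array_equal(reintegrate(once, 60).counts, once.counts)

    def test_non_divisible_target_rejected(self):
        with pytest.raises(InvalidConfigError):
            reintegrate(series_60s([1]), 90)


class TestDetectNonwear:
    def test_all_zero_day_has_no_wear(self):
        mask = detect_nonwear(series_60s(np.zeros(1440)))
        assert mask.sum() == 0

    @pytest.mark.parametrize("run,expected_wear", [(20, 20), (21, 0)])
    def test_20_minute_boundary_is_strict(self, run, expected_wear):
        # zero runs of exactly 20 min are wear; 21 min is non-wear
        cpm = [50] * 5 + [0] * run + [50] * 5
        mask = detect_nonwear(series_60s(cpm))
        assert mask[5 : 5 + run].sum() == expected_wear
        assert mask[:5].all() and mask[5 + run :].all()

    def test_zero_run_at_day_edge(self):
        cpm = [0] * 30 + [50] * 10
        mask = detect_nonwear(series_60s(cpm))
        assert not mask[:30].any() and mask[30:].all()


class TestSummarizeDay:
    @pytest.mark.parametrize(
        "cpm,band",
        [(99, "sedentary"), (100, "light"), (1951, "light"),
         (1952, "moderate"), (5723, "moderate"), (5724, "vigorous")],
    )
    def test_cutpoint_boundaries(self, cpm, band):
        s = series_60s([cpm])
        summary = summarize_day(s, np.array([True]))
        assert getattr(summary, f"{band}_min") == 1

    @pytest.mark.parametrize("wear,valid", [(600, False), (601, True)])
    def test_valid_day_boundary_is_strict(self, wear, valid):
        s = series_60s([150] * wear)
        assert summarize_day(s).valid is valid

    def test_empty_day_is_invalid(self):
        summary = summarize_day(series_60s([]))
        assert summary.wear_min == 0 and not summary.valid

    def test_total_counts_include_whole_day(self):
        cpm = [100] * 10 + [0] * 30 + [200] * 10
        summary = summarize_day(series_60s(cpm))
        assert summary.total_counts == 100 * 10 + 200 * 10
        assert summary.wear_min == 20

    def test_intensity_minutes_partition_wear(self):
        rng = np.random.default_rng(2)
        cpm = rng.integers(0, 8000, 1000)
        summary = summarize_day(series_60s(cpm))
        parts = (summary.sedentary_min + summary.light_min
                 + summary.moderate_min + summary.vigorous_min)
        assert parts == summary.wear_min

    def test_monotone_adding_nonzero_epochs(self):
        base = [150] * 300
        w0 = summarize_day(series_60s(base)).wear_min
        w1 = summarize_day(series_60s(base + [150] * 50)).wear_min
        assert w1 >= w0


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_pipeline_reproduces_planned_truth(seed):
    """Round-trip property: plan -> epochs -> processing == planned truth."""
    plan = random_epoch_day_plan(np.random.default_rng(seed))
    series, truth = generate_epoch_day(plan)
    s60 = reintegrate(series, 60)
    got = summarize_day(s60, detect_nonwear(s60))
    assert got.as_row() == truth.as_row()


class TestIncludeSubjects:
    @staticmethod
    def _summaries(spec):
        """spec: mapping subject -> (n_valid, n_invalid) day counts."""
        plans = []
        for sid, (nv, ni) in spec.items():
            for d in range(nv):
                plans.append(EpochDayPlan(sid, BASE_DATE + timedelta(days=d),
                                          bouts=((601, "light"),), seed=d))
            for d in range(ni):
                plans.append(EpochDayPlan(sid, BASE_DATE + timedelta(days=nv + d),
                                          bouts=((300, "light"),), seed=d))
        return summaries_to_frame(truth for _, truth in map(generate_epoch_day, plans))

    def test_21_valid_days_included_20_excluded(self):
        cohort = include_subjects(self._summaries({"in": (21, 3), "out": (20, 4)}))
        assert set(cohort.data["subject_id"]) == {"in"}
        assert cohort.exclusions["subject_id"].tolist() == ["out"]
        assert cohort.exclusions["n_valid_days"].tolist() == [20]
        # retained days are the valid ones only
        assert cohort.days_per_subject()["in"] == 21

    def test_attrition_61_to_50(self):
        spec = {f"S{i:02d}": ((21, 0) if i < 50 else (15, 6)) for i in range(61)}
        cohort = include_subjects(self._summaries(spec))
        assert cohort.n_subjects == 50
        assert len(cohort.exclusions) == 11

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            cohort = include_subjects(summaries_to_frame([]))
        assert cohort.n_days == 0 and cohort.exclusions.empty


def test_process_stream_end_to_end(tmp_path):
    rng = np.random.default_rng(9)
    plans = [random_epoch_day_plan(rng, subject_id="P1",
                                   date=BASE_DATE + timedelta(days=d))
             for d in range(3)]
    series = []
    truths = []
    for plan in plans:
        s, t = generate_epoch_day(plan)
        series.append(s)
        truths.append(t)
    p = tmp_path / "stream.csv"
    write_epoch_stream(series, p)
    got = process_stream(read_epoch_file(p))
    expected = summaries_to_frame(truths)
    pd.testing.assert_frame_equal(
        got.sort_values("date").reset_index(drop=True),
        expected.sort_values("date").reset_index(drop=True),
    )
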