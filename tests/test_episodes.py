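"""Episode detection, alert splitting/classification, and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoval.episodes import (
    AlertSegment,
    Episode,
    brute_force_matcher,
    classify_alerts,
    detect_alert_episodes,
    detect_episodes,
    detect_hypotension_episodes,
    performance_from_counts,
    score_predictions,
    split_alerts,
)

from conftest import make_series, random_stress_series

MIN = 60.0


def ep(start_min, end_min, kind="hypotension", pid="P01"):
    return Episode(pid, kind, start_min * MIN, end_min * MIN, 1)


def seg(start_min, end_min, pid="P01"):
    return AlertSegment(pid, start_min * MIN, end_min * MIN)


class TestDetect:
    def test_three_qualifying_samples_make_one_minute(self):
        s = make_series([70, 60, 60, 60, 70])
        (e,) = detect_hypotension_episodes(s)
        assert (e.start, e.end, e.n_samples) == (20.0, 80.0, 3)
        assert e.duration == 60.0

    def test_two_samples_fail_the_minute_rule(self):
        s = make_series([70, 60, 60, 70])
        assert detect_hypotension_episodes(s) == []

    def test_sample_exactly_at_threshold_never_qualifies(self):
        s = make_series([64, 64, 64, 65])
        (e,) = detect_hypotension_episodes(s)
        assert e.end == 60.0 and e.n_samples == 3

    def test_run_to_series_end_holds_one_dt(self):
        s = make_series([64, 64, 64])
        (e,) = detect_hypotension_episodes(s)
        assert (e.start, e.end) == (0.0, 60.0)

    def test_isolated_hpi_record_is_no_alert(self):
        s = make_series([70, 70, 70], [50, 90, 50])
        assert detect_alert_episodes(s) == []

    def test_two_hpi_records_make_an_alert(self):
        s = make_series([70] * 4, [50, 85, 90, 50])
        (a,) = detect_alert_episodes(s)
        assert (a.start, a.end, a.n_samples) == (20.0, 60.0, 2)

    def test_missing_map_breaks_both_kinds(self):
        s = make_series([60, None, 60, 60, 60], [90, 90, 90, 90, 20])
        assert detect_hypotension_episodes(s) == [
            Episode("P01", "hypotension", 40.0, 100.0, 3, (40.0, 60.0, 80.0))
        ]
        # the HPI run is split by the missing MAP sample: 1 + 3 records
        (a,) = detect_alert_episodes(s)
        assert (a.start, a.n_samples) == (40.0, 2)

    def test_gap_terminates_run(self):
        s = make_series([60, 60, 60, 60, 60, 60], t=[0, 20, 40, 700, 720, 740])
        eps = detect_hypotension_episodes(s)
        assert [(e.start, e.end) for e in eps] == [(0.0, 60.0), (700.0, 760.0)]

    def test_empty_series(self):
        s = make_series([])
        assert detect_episodes(s, "map", 65, "below") == []


class TestSplit:
    def test_forty_minute_alert_splits_at_15(self):
        segs = split_alerts([ep(0, 40, kind="alert")], hypo=[])
        assert [(g.start / 60, g.end / 60) for g in segs] == [
            (0, 15),
            (15, 30),
            (30, 40),
        ]

    def test_split_at_end_of_first_hypotension(self):
        segs = split_alerts([ep(0, 20, kind="alert")], hypo=[ep(8, 10)])
        assert [(g.start / 60, g.end / 60) for g in segs] == [(0, 10), (10, 20)]

    def test_short_alert_unchanged(self):
        segs = split_alerts([ep(0, 5, kind="alert")], hypo=[])
        assert [(g.start / 60, g.end / 60) for g in segs] == [(0, 5)]

    def test_remainder_needs_a_sample(self):
        alert = Episode("P01", "alert", 0.0, 16 * MIN, 48, tuple(np.arange(48) * 20.0))
        # samples run to 940 s; remainder (900, 960) contains samples 900..940
        segs = split_alerts([alert], hypo=[])
        assert len(segs) == 2
        alert2 = Episode("P01", "alert", 0.0, 16 * MIN, 45, tuple(np.arange(45) * 20.0))
        # last sample at 880 s: nothing remains at/after the 900-s cut
        assert len(split_alerts([alert2], hypo=[])) == 1


class TestClassify:
    def test_repeated_alerts_before_one_hypotension(self):
        # three alerts precede a single hypotension onset: first is true,
        # the later two are ignored (not false)
        segs = [seg(0, 2), seg(3, 5), seg(6, 8)]
        hypo = [ep(10, 13)]
        out = classify_alerts(segs, hypo)
        assert [g.classification for g in out] == ["true_alert", "ignored", "ignored"]
        assert out[0].time_to_first == 10 * MIN

    def test_one_alert_claims_multiple_onsets(self):
        segs = [seg(0, 2)]
        hypo = [ep(4, 6), ep(12, 14)]
        (g,) = classify_alerts(segs, hypo)
        assert g.classification == "true_alert"
        assert [h.start / 60 for h in g.predicted] == [4, 12]
        assert g.time_to_first == 4 * MIN

    def test_onset_outside_window_is_false(self):
        (g,) = classify_alerts([seg(0, 2)], [ep(16, 18)])
        assert g.classification == "false_alert" and g.time_to_first is None

    def test_onset_at_window_boundary_is_claimed(self):
        (g,) = classify_alerts([seg(0, 2)], [ep(15, 17)])
        assert g.classification == "true_alert"

    def test_ongoing_hypotension_not_claimable(self):
        (g,) = classify_alerts([seg(5, 7)], [ep(4, 8)])
        assert g.classification == "false_alert"
        assert g.starts_during_hypotension


class TestScore:
    def test_degenerate_single_counts(self):
        perf = performance_from_counts(1, 1, 1, 1, [120.0])
        assert perf.sensitivity == 1.0 and perf.sensitivity_ci == (1.0, 1.0)
        assert perf.ppv == 1.0 and perf.ppv_ci == (1.0, 1.0)

    def test_zero_denominators_flagged(self):
        perf = performance_from_counts(0, 0, 0, 0)
        assert perf.sensitivity is None and perf.ppv is None
        assert len(perf.flags) == 2

    def test_score_pipeline_counts(self):
        hypo = [ep(10, 13), ep(30, 32)]
        segs = classify_alerts(
            split_alerts([ep(0, 2, kind="alert"), ep(40, 42, kind="alert")], hypo),
            hypo,
        )
        perf = score_predictions(segs, hypo)
        assert (perf.n_hypotension, perf.n_predicted) == (2, 1)
        assert (perf.n_alerts, perf.n_true_alerts, perf.n_false_alerts) == (2, 1, 1)


class TestProperties:
    def test_episodes_disjoint_sorted(self):
        for seed in range(30):
            s = random_stress_series(seed)
            for eps in (detect_hypotension_episodes(s), detect_alert_episodes(s)):
                for a, b in zip(eps, eps[1:]):
                    assert a.end <= b.start

    def test_hypotension_union_equals_qualifying_runs(self):
        # every sub-threshold sample inside a detected episode; episodes of
        # k >= 3 consecutive samples at 20 s
        s = random_stress_series(7)
        eps = detect_hypotension_episodes(s)
        for e in eps:
            assert e.n_samples >= 3
            inside = (s.t >= e.start) & (s.t < e.end)
            vals = s.map_mmHg[inside]
            assert np.all(vals[~np.isnan(vals)] < 65.0)

    def test_each_onset_claimed_once(self):
        for seed in range(30):
            s = random_stress_series(seed)
            hypo = detect_hypotension_episodes(s)
            segs = classify_alerts(
                split_alerts(detect_alert_episodes(s), hypo), hypo
            )
            claimed = [h.start for g in segs for h in g.predicted]
            assert len(claimed) == len(set(claimed))
            perf = score_predictions(segs, hypo)
            assert perf.n_predicted <= perf.n_hypotension
            assert perf.n_true_alerts <= perf.n_alerts

    def test_time_translation_invariance(self):
        s = random_stress_series(11)
        shifted = make_series(
            s.map_mmHg, s.hpi, patient_id=s.patient_id, t=s.t + 12345.0
        )
        a = brute_force_matcher(s).to_dict()
        b = brute_force_matcher(shifted).to_dict()
        for k in ("n_hypotension", "n_predicted", "n_alerts", "n_true_alerts"):
            assert a[k] == b[k]

    @pytest.mark.parametrize("seed", range(60))
    def test_oracle_equivalence(self, seed):
        """detect/split/classify agrees exactly with the exhaustive scan."""
        s = random_stress_series(seed)
        hypo = detect_hypotension_episodes(s)
        segs = classify_alerts(split_alerts(detect_alert_episodes(s), hypo), hypo)
        fast = score_predictions(segs, hypo)
        slow = brute_force_matcher(s)
        for k in (
            "n_hypotension",
            "n_predicted",
            "n_alerts",
            "n_true_alerts",
            "n_false_alerts",
            "n_ignored_alerts",
        ):
            assert getattr(fast, k) == getattr(slow, k), k
        assert sorted(fast.times_to_hypotension) == pytest.approx(
            sorted(slow.times_to_hypotension)
        )

    @given(
        st.lists(
            st.tuples(
                st.one_of(st.none(), st.integers(min_value=65 - 6, max_value=65 + 6)),
                st.one_of(st.none(), st.integers(min_value=85 - 6, max_value=100)),
            ),
            max_size=40,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_oracle_equivalence_on_arbitrary_traces(self, rows):
        """Any MAP/HPI pattern near the thresholds scores like the slow scan."""
        map_vals = [m for m, _ in rows]
        hpi_vals = [h for _, h in rows]
        s = make_series(map_vals, hpi_vals)
        hypo = detect_hypotension_episodes(s)
        segs = classify_alerts(split_alerts(detect_alert_episodes(s), hypo), hypo)
        fast = score_predictions(segs, hypo)
        slow = brute_force_matcher(s)
        assert fast.to_dict() == slow.to_dict()

    def test_all_sub_threshold_series_is_one_episode(self):
        s = make_series([60] * 50)
        (e,) = detect_hypotension_episodes(s)
        assert (e.start, e.end) == (0.0, 1000.0)
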