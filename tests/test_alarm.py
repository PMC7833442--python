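"""Alarm rule: brute-force oracle agreement, boundary strictness, streaming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afmonitor.alarm import (
    AlarmRule,
    StreamScanner,
    dispatch,
    scan_trace,
)
from afmonitor.channels import ProbabilityTrace
from oracles import bruteforce_alarm_runs


def _trace(probs, spacing=1.0, t0=0.0):
    n = len(probs)
    return ProbabilityTrace(times=t0 + spacing * np.arange(n), probabilities=probs)


def _as_tuples(events):
    return sorted(
        (e.run_start, e.detection_time, e.run_end, e.max_probability) for e in events
    )


RULE = AlarmRule(threshold=0.5, min_duration=30.0, max_gap=10.0)


class TestScanTrace:
    def test_sustained_run_detected_with_expected_times(self):
        events = scan_trace(_trace([0.6] * 40), RULE)
        assert len(events) == 1
        ev = events[0]
        assert ev.run_start == 0.0
        assert ev.detection_time == 30.0
        assert ev.run_end == 39.0
        assert ev.max_probability == pytest.approx(0.6)

    def test_subthreshold_trace_raises_nothing(self):
        assert scan_trace(_trace([0.4] * 200), RULE) == []

    def test_twentynine_seconds_is_not_enough(self):
        # samples at 0..29 s span 29 s: below the 30-s minimum
        probs = [0.9] * 30 + [0.4]
        assert scan_trace(_trace(probs), RULE) == []

    def test_thirty_second_span_is_exactly_enough(self):
        probs = [0.9] * 31 + [0.4]
        events = scan_trace(_trace(probs), RULE)
        assert len(events) == 1
        assert events[0].run_end - events[0].run_start == pytest.approx(30.0)

    def test_probability_exactly_at_threshold_does_not_count(self):
        # "above 0.5" is strict: a constant 0.5 trace never alarms
        assert scan_trace(_trace([0.5] * 100), RULE) == []
        # and an exact-threshold sample splits an otherwise long run
        probs = [0.9] * 20 + [0.5] + [0.9] * 20
        assert scan_trace(_trace(probs), RULE) == []

    def test_two_separated_runs_give_two_events(self):
        probs = [0.8] * 36 + [0.2] * 60 + [0.8] * 36
        events = scan_trace(_trace(probs), RULE)
        assert len(events) == 2

    def test_data_gap_breaks_a_run(self):
        # 20 super-threshold samples, a 12-s hole, then 20 more: no event,
        # because neither half spans 30 s and the gap may not bridge them
        times = np.concatenate([np.arange(20.0), 31.0 + np.arange(20.0)])
        trace = ProbabilityTrace(times=times, probabilities=np.full(40, 0.9))
        assert scan_trace(trace, RULE) == []

    def test_unsorted_trace_rejected(self):
        trace = ProbabilityTrace(times=[0.0, 1.0], probabilities=[0.6, 0.6])
        trace.times = np.array([1.0, 0.0])
        with pytest.raises(ValueError):
            scan_trace(trace, RULE)

    def test_matches_bruteforce_oracle_on_random_traces(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 120))
            probs = rng.uniform(0, 1, n)
            # sprinkle occasional gaps to exercise the gap-break logic
            spacing = np.where(rng.uniform(size=n) < 0.05, 15.0, 1.0)
            times = np.cumsum(spacing)
            rule = AlarmRule(threshold=0.5, min_duration=10.0, max_gap=10.0)
            got = _as_tuples(scan_trace(ProbabilityTrace(times, probs), rule))
            want = bruteforce_alarm_runs(times.tolist(), probs.tolist(), 0.5, 10.0, 10.0)
            assert got == pytest.approx(want)


class TestMonotonicity:
    def test_events_at_high_threshold_nest_inside_low_threshold_events(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            probs = rng.uniform(0, 1, 300)
            trace = _trace(probs)
            low = scan_trace(trace, AlarmRule(threshold=0.4, min_duration=20.0))
            high = scan_trace(trace, AlarmRule(threshold=0.6, min_duration=20.0))
            for ev in high:
                assert any(
                    lo.run_start <= ev.run_start and ev.run_end <= lo.run_end
                    for lo in low
                )

    def test_lowering_threshold_can_merge_runs(self):
        # the reason event *count* is not monotone in the threshold
        probs = [0.9] * 36 + [0.55] * 60 + [0.9] * 36
        trace = _trace(probs)
        assert len(scan_trace(trace, AlarmRule(threshold=0.6, min_duration=30.0))) == 2
        assert len(scan_trace(trace, AlarmRule(threshold=0.5, min_duration=30.0))) == 1


class _Rec:
    patient_id = "p1"
    assigned_physician = "dr-a"


class TestDispatch:
    def _event(self):
        return scan_trace(_trace([0.8] * 40), RULE)[0]

    def test_message_addressed_to_assigned_physician(self):
        msg = dispatch(self._event(), _Rec())
        assert msg.physician_id == "dr-a"
        assert msg.patient_id == "p1"
        assert msg.dispatch_time == msg.detection_time
        assert not msg.latency_violation
        assert msg.evidence_start == pytest.approx(self._event().run_start - 60.0)
        assert msg.evidence_end == pytest.approx(self._event().run_end)

    def test_missing_physician_is_an_error(self):
        class NoPhys:
            patient_id = "p2"
            assigned_physician = None

        with pytest.raises(ValueError):
            dispatch(self._event(), NoPhys())

    def test_late_dispatch_flags_latency_contract(self):
        ev = self._event()
        msg = dispatch(ev, _Rec(), dispatch_time=ev.detection_time + 400.0)
        assert msg.latency_violation
        ok = dispatch(ev, _Rec(), dispatch_time=ev.detection_time + 299.0)
        assert not ok.latency_violation


class TestStreamScanner:
    def test_chunked_feed_equals_batch_scan(self):
        probs = np.asarray([0.6] * 40)
        trace = _trace(probs)
        scanner = StreamScanner(RULE)
        detected = []
        for i in range(0, 40, 5):
            detected += scanner.feed(trace.times[i : i + 5], probs[i : i + 5])
        assert len(detected) == 1
        assert _as_tuples(scanner.finalize()) == _as_tuples(scan_trace(trace, RULE))

    def test_repolling_without_new_data_emits_nothing(self):
        probs = np.asarray([0.9] * 40)
        trace = _trace(probs)
        scanner = StreamScanner(RULE)
        first = scanner.feed(trace.times, probs)
        assert len(first) == 1
        assert scanner.feed([], []) == []
        assert len(scanner.finalize()) == 1

    def test_random_chunkings_match_batch(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 200))
            probs = rng.uniform(0, 1, n)
            spacing = np.where(rng.uniform(size=n) < 0.05, 15.0, 1.0)
            times = np.cumsum(spacing)
            rule = AlarmRule(threshold=0.5, min_duration=8.0, max_gap=10.0)
            scanner = StreamScanner(rule)
            i = 0
            while i < n:
                step = int(rng.integers(1, 12))
                scanner.feed(times[i : i + step], probs[i : i + step])
                i += step
            batch = scan_trace(ProbabilityTrace(times, probs), rule)
            assert _as_tuples(scanner.finalize()) == _as_tuples(batch)

    def test_time_going_backwards_rejected(self):
        scanner = StreamScanner(RULE)
        scanner.feed([0.0, 1.0], [0.6, 0.6])
        with pytest.raises(ValueError):
            scanner.feed([0.5], [0.6])
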