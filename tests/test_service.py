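"""Monitor service: registry, pipeline composition, feedback traffic light."""

from datetime import date

import numpy as np
import pytest

from afmonitor import channels
from afmonitor.alarm import AlarmRule
from afmonitor.biomarkers import RegionOfInterest, compute_biomarkers
from afmonitor.detector import WindowingConfig, predict_trace
from afmonitor.rhythm import AF, NSR, EpisodeSchedule, RhythmParams, generate_recording
from afmonitor.service import (
    AF_CONFIRMED,
    AF_REJECTED,
    AuthorizationError,
    Diagnosis,
    GREEN,
    ORANGE,
    PatientRecord,
    RED,
    Registry,
)

KEY = "key-123"


def _record(pid="p1", physician="dr-house"):
    return PatientRecord(
        patient_id=pid,
        assigned_physician=physician,
        service_start=date(2026, 1, 1),
        service_end=date(2026, 12, 31),
        channel_key=KEY,
    )


@pytest.fixture
def registry(tmp_path):
    reg = Registry(tmp_path / "svc")
    reg.register_patient(_record())
    return reg


def _paroxysmal_series(seed=50):
    schedule = EpisodeSchedule([(NSR, 600), (AF, 300), (NSR, 600)])
    return generate_recording(RhythmParams(seed=seed), schedule)


class TestRegistry:
    def test_registration_creates_empty_channels(self, registry):
        assert len(registry) == 1
        rr = registry.rr_channel_path("p1", KEY)
        res = registry.result_channel_path("p1", KEY)
        assert rr.exists() and res.exists()
        assert rr.read_text().splitlines()[1] == "timestamp,value"

    def test_duplicate_patient_rejected(self, registry):
        with pytest.raises(ValueError):
            registry.register_patient(_record())

    def test_service_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            PatientRecord(
                patient_id="x", assigned_physician="dr",
                service_start=date(2026, 5, 1), service_end=date(2026, 4, 1),
                channel_key="k",
            )

    def test_registry_persists_across_instances(self, registry):
        again = Registry(registry.root)
        assert "p1" in again
        assert again.record("p1").assigned_physician == "dr-house"

    def test_channel_access_requires_key(self, registry):
        with pytest.raises(AuthorizationError):
            registry.rr_channel_path("p1", "wrong-key")
        with pytest.raises(KeyError):
            registry.rr_channel_path("ghost", KEY)

    def test_chunked_upload_equals_one_shot(self, tmp_path):
        reg_a = Registry(tmp_path / "a")
        reg_b = Registry(tmp_path / "b")
        reg_a.register_patient(_record())
        reg_b.register_patient(_record())
        series = _paroxysmal_series()
        reg_a.append_rr("p1", KEY, series.intervals)
        for chunk in np.array_split(series.intervals, 7):
            reg_b.append_rr("p1", KEY, chunk)
        a = reg_a.rr_channel_path("p1", KEY).read_bytes()
        b = reg_b.rr_channel_path("p1", KEY).read_bytes()
        assert a == b


class TestMonitorPipeline:
    def test_af_episode_raises_alarm_to_assigned_physician(self, registry, trained_model):
        series = _paroxysmal_series()
        registry.append_rr("p1", KEY, series.intervals)
        outcome = registry.run_patient_monitor("p1", KEY, trained_model)
        assert outcome.wrote_results
        assert len(outcome.new_messages) >= 1
        assert all(m.physician_id == "dr-house" for m in outcome.new_messages)
        log = (registry.root / "patients" / "p1" / "alarms.log").read_text()
        assert "physician=dr-house" in log

    def test_pure_nsr_recording_raises_no_alarm(self, registry, trained_model):
        series = generate_recording(
            RhythmParams(seed=51), EpisodeSchedule([(NSR, 1500)])
        )
        registry.append_rr("p1", KEY, series.intervals)
        outcome = registry.run_patient_monitor("p1", KEY, trained_model)
        assert outcome.wrote_results
        assert outcome.new_messages == []

    def test_monitor_is_idempotent_without_new_data(self, registry, trained_model):
        registry.append_rr("p1", KEY, _paroxysmal_series().intervals)
        first = registry.run_patient_monitor("p1", KEY, trained_model)
        res_path = registry.result_channel_path("p1", KEY)
        bytes_after_first = res_path.read_bytes()
        second = registry.run_patient_monitor("p1", KEY, trained_model)
        assert not second.wrote_results
        assert second.n_windows_new == 0 and second.new_messages == []
        assert res_path.read_bytes() == bytes_after_first
        assert first.n_windows_total == second.n_windows_total

    def test_pipeline_equals_manual_stage_composition(self, registry, trained_model, tmp_path):
        series = _paroxysmal_series()
        registry.append_rr("p1", KEY, series.intervals)
        wcfg = WindowingConfig(window_len=100, stride=10)
        registry.run_patient_monitor("p1", KEY, trained_model, windowing=wcfg)
        # manual composition: read -> predict -> write
        read_back = channels.read_rr_channel(registry.rr_channel_path("p1", KEY))
        trace = predict_trace(trained_model, read_back, wcfg)
        manual = tmp_path / "manual.csv"
        channels.write_result_channel(trace, manual, epoch=read_back.t_origin)
        assert manual.read_bytes() == registry.result_channel_path("p1", KEY).read_bytes()

    def test_unregistered_patient_rejected(self, registry, trained_model):
        with pytest.raises(KeyError):
            registry.run_patient_monitor("ghost", KEY, trained_model)

    def test_out_of_service_period_flagged(self, registry, trained_model):
        registry.append_rr("p1", KEY, _paroxysmal_series().intervals)
        outcome = registry.run_patient_monitor(
            "p1", KEY, trained_model, today=date(2027, 6, 1)
        )
        assert outcome.out_of_service_period


class TestPhysicianReview:
    def test_full_record_roi_reproduces_global_biomarkers(self, registry, trained_model):
        series = _paroxysmal_series()
        registry.append_rr("p1", KEY, series.intervals)
        registry.run_patient_monitor("p1", KEY, trained_model)
        read_back = channels.read_rr_channel(registry.rr_channel_path("p1", KEY))
        roi = RegionOfInterest(0.0, float(read_back.beat_times[-1]) + 1.0)
        report = registry.physician_report("p1", KEY, roi)
        want = compute_biomarkers(read_back)
        assert report.biomarkers == want
        assert len(report.roi_colours) == len(read_back)
        assert 0.0 <= report.max_probability <= 1.0

    def test_report_on_empty_record_is_an_error(self, registry):
        with pytest.raises(ValueError):
            registry.physician_report("p1", KEY, RegionOfInterest(0.0, 10.0))

    def test_rejected_diagnosis_keeps_patient_monitored(self, registry, trained_model):
        registry.append_rr("p1", KEY, _paroxysmal_series().intervals)
        registry.run_patient_monitor("p1", KEY, trained_model)
        registry.record_diagnosis(Diagnosis(
            patient_id="p1", physician_id="dr-house", outcome=AF_REJECTED,
            time=2000.0, roi_start=500.0, roi_end=1000.0,
        ))
        assert "p1" in registry
        assert registry.diagnoses("p1")[-1].outcome == AF_REJECTED
        # monitoring continues: a fresh poll still works
        registry.append_rr("p1", KEY, np.full(100, 850.0))
        outcome = registry.run_patient_monitor("p1", KEY, trained_model)
        assert outcome.n_windows_new > 0

    def test_unknown_outcome_rejected(self, registry):
        with pytest.raises(ValueError):
            registry.record_diagnosis(Diagnosis(
                patient_id="p1", physician_id="dr", outcome="maybe",
                time=0.0, roi_start=0.0, roi_end=1.0,
            ))


class TestFeedback:
    def test_green_orange_red_transitions(self, registry, trained_model):
        # fresh data, no alarm -> green
        nsr = generate_recording(RhythmParams(seed=60), EpisodeSchedule([(NSR, 200)]))
        registry.append_rr("p1", KEY, nsr.intervals)
        now = float(np.sum(nsr.intervals) / 1000.0) + 10.0
        assert registry.feedback_status("p1", KEY, now).level == GREEN

        # AF episode raises an alarm -> orange while unreviewed
        af = generate_recording(RhythmParams(seed=61), EpisodeSchedule([(AF, 600), (NSR, 600)]))
        registry.append_rr("p1", KEY, af.intervals)
        registry.run_patient_monitor("p1", KEY, trained_model)
        now += float(np.sum(af.intervals) / 1000.0)
        status = registry.feedback_status("p1", KEY, now)
        assert status.level == ORANGE

        # physician confirms AF -> red
        registry.record_diagnosis(Diagnosis(
            patient_id="p1", physician_id="dr-house", outcome=AF_CONFIRMED,
            time=now, roi_start=0.0, roi_end=now,
        ))
        assert registry.feedback_status("p1", KEY, now + 1.0).level == RED

    def test_signal_interruption_turns_orange(self, registry):
        nsr = generate_recording(RhythmParams(seed=62), EpisodeSchedule([(NSR, 100)]))
        registry.append_rr("p1", KEY, nsr.intervals)
        last = float(np.sum(nsr.intervals) / 1000.0)
        assert registry.feedback_status("p1", KEY, last + 60.0).level == GREEN
        assert registry.feedback_status("p1", KEY, last + 16 * 60.0).level == ORANGE

    def test_no_data_at_all_is_an_interruption(self, registry):
        assert registry.feedback_status("p1", KEY, 0.0).level == ORANGE

    def test_rejection_clears_orange_back_to_green(self, registry, trained_model):
        af = generate_recording(RhythmParams(seed=63), EpisodeSchedule([(AF, 600)]))
        registry.append_rr("p1", KEY, af.intervals)
        registry.run_patient_monitor("p1", KEY, trained_model)
        now = float(np.sum(af.intervals) / 1000.0)
        assert registry.feedback_status("p1", KEY, now).level == ORANGE
        registry.record_diagnosis(Diagnosis(
            patient_id="p1", physician_id="dr-house", outcome=AF_REJECTED,
            time=now, roi_start=0.0, roi_end=now,
        ))
        assert registry.feedback_status("p1", KEY, now + 1.0).level == GREEN
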