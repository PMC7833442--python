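"""End-to-end service walkthrough: register, monitor, alarm, review, feedback.

Registers a patient, uploads a paroxysmal recording (10 min NSR, 5 min AF,
10 min NSR), runs the monitor poll, prints the alarm messages and the
physician report over the episode, records the physician's confirmation and
shows the traffic light walking orange -> red.  Everything is simulated in
a temporary directory; timestamps are data time, never wall clock.
"""

import tempfile
from datetime import date
from pathlib import Path

import numpy as np

from afmonitor import (
    AF,
    AF_CONFIRMED,
    Diagnosis,
    EpisodeSchedule,
    NSR,
    PatientRecord,
    Registry,
    RegionOfInterest,
    RhythmParams,
    WindowingConfig,
    generate_recording,
    make_benchmark,
    make_windows,
    train,
)

# train a detector on a small benchmark (seconds, not minutes)
recordings = make_benchmark(n_per_class=40, beats=120, seed=7)
wcfg = WindowingConfig(window_len=100, stride=100)
windows = [w for rec in recordings for w in make_windows(rec, wcfg)]
model = train(windows, [w.label for w in windows], seed=0)

with tempfile.TemporaryDirectory() as tmp:
    registry = Registry(Path(tmp) / "service")
    registry.register_patient(PatientRecord(
        patient_id="patient-001", assigned_physician="dr-adams",
        service_start=date(2026, 1, 1), service_end=date(2026, 12, 31),
        channel_key="demo-key",
    ))

    series = generate_recording(
        RhythmParams(seed=11), EpisodeSchedule([(NSR, 600), (AF, 300), (NSR, 600)])
    )
    registry.append_rr("patient-001", "demo-key", series.intervals)
    outcome = registry.run_patient_monitor("patient-001", "demo-key", model)
    print(f"monitor poll: {outcome.n_windows_total} windows scored, "
          f"{len(outcome.new_messages)} alarm(s)")
    for m in outcome.new_messages:
        print(f"  alarm -> {m.physician_id}: detection at {m.detection_time:.0f} s, "
              f"evidence {m.evidence_channel}[{m.evidence_start:.0f}, {m.evidence_end:.0f}] s")

    now = float(series.beat_times[-1])
    print("feedback before review:",
          registry.feedback_status("patient-001", "demo-key", now).level)

    # physician reviews the alarm evidence over the episode region
    msg = outcome.new_messages[0]
    roi = RegionOfInterest(max(msg.evidence_start, 0.0), msg.evidence_end)
    report = registry.physician_report("patient-001", "demo-key", roi)
    print()
    print(report.summary())
    print()

    registry.record_diagnosis(Diagnosis(
        patient_id="patient-001", physician_id="dr-adams", outcome=AF_CONFIRMED,
        time=now, roi_start=roi.start, roi_end=roi.end,
    ))
    status = registry.feedback_status("patient-001", "demo-key", now + 1.0)
    print(f"feedback after confirmation: {status.level} — {status.message}")
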