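"""Patient registry and monitoring service.

Ties the stages into the end-to-end telemonitoring loop:

* a **registry** of patient records (JSON file), each with an assigned
  physician, a service period and an opaque channel key that gates access to
  the patient's two channel files (``RR_interval_data``,
  ``AF_detection_result``);
* a per-patient **monitor** that polls the RR channel, scores new windows
  with the detector, publishes the probability trace to the result channel
  and raises alarm messages under the sustained-threshold rule;
* a **physician report** over a selected region of interest: probability
  overview, probability-coloured RR trace and the HRV biomarker panel, plus
  an audit trail of accept/reject diagnoses;
* a **traffic-light feedback** status per patient: green (all well), orange
  (unreviewed alarm or interrupted data stream), red (physician-confirmed
  AF).  Red always requires a physician's confirmation — the machine alone
  never tells a patient to seek help immediately; diagnostic authority stays
  with the physician.

All timing is simulated (timestamps carried in the data), never wall-clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import channels
from .alarm import AlarmMessage, AlarmRule, dispatch, format_alarm_log, scan_trace
from .biomarkers import (
    BiomarkerSet,
    RegionOfInterest,
    compute_biomarkers,
    extract_region,
    probability_colour_map,
)
from .channels import ProbabilityTrace, RR_CHANNEL, RESULT_CHANNEL
from .detector import DetectorModel, WindowingConfig, make_windows, predict_trace
from .rhythm import RRSeries

__all__ = [
    "PatientRecord",
    "Registry",
    "MonitorOutcome",
    "PhysicianReport",
    "FeedbackStatus",
    "Diagnosis",
    "AF_CONFIRMED",
    "AF_REJECTED",
    "GREEN",
    "ORANGE",
    "RED",
]

AF_CONFIRMED = "AF_confirmed"
AF_REJECTED = "AF_rejected"
GREEN, ORANGE, RED = "green", "orange", "red"

REGISTRY_FORMAT = "afmonitor-registry-v1"

#: No new RR data for longer than this (simulated seconds) counts as a
#: signal interruption and turns the feedback light orange.
DATA_INTERRUPTION_S = 15 * 60.0


class AuthorizationError(PermissionError):
    pass


@dataclass(frozen=True)
class PatientRecord:
    """Registry entry for one monitored patient."""

    patient_id: str
    assigned_physician: str
    service_start: date
    service_end: date
    channel_key: str
    credentials: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.service_end < self.service_start:
            raise ValueError(
                f"service_end {self.service_end} precedes service_start {self.service_start}"
            )

    def to_json(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "assigned_physician": self.assigned_physician,
            "service_start": self.service_start.isoformat(),
            "service_end": self.service_end.isoformat(),
            "channel_key": self.channel_key,
            "credentials": self.credentials,
        }

    @classmethod
    def from_json(cls, d: dict) -> "PatientRecord":
        return cls(
            patient_id=d["patient_id"],
            assigned_physician=d["assigned_physician"],
            service_start=date.fromisoformat(d["service_start"]),
            service_end=date.fromisoformat(d["service_end"]),
            channel_key=d["channel_key"],
            credentials=d.get("credentials", ""),
        )


@dataclass
class MonitorOutcome:
    """Result of one monitor poll."""

    patient_id: str
    n_windows_total: int
    n_windows_new: int
    new_messages: List[AlarmMessage]
    wrote_results: bool
    out_of_service_period: bool = False


@dataclass
class PhysicianReport:
    """Evidence bundle for physician review of one region of interest."""

    patient_id: str
    trace: ProbabilityTrace
    max_probability: float
    fraction_above_half: float
    roi: RegionOfInterest
    roi_series: RRSeries
    roi_colours: np.ndarray
    biomarkers: BiomarkerSet

    def summary(self) -> str:
        lines = [
            f"Patient {self.patient_id}: {len(self.trace)} analysis windows",
            f"  max AF probability      {self.max_probability:.3f}",
            f"  fraction of windows>0.5 {self.fraction_above_half:.3f}",
            f"  ROI [{self.roi.start:.1f}, {self.roi.end:.1f}) s — "
            f"{self.biomarkers.n_beats} beats",
            "",
            self.biomarkers.table(),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class Diagnosis:
    patient_id: str
    physician_id: str
    outcome: str
    time: float
    roi_start: float
    roi_end: float


@dataclass(frozen=True)
class FeedbackStatus:
    level: str
    message: str
    issued_at: float


class Registry:
    """File-backed patient registry with per-patient channel storage.

    Layout under ``root``::

        registry.json
        patients/<id>/RR_interval_data.csv
        patients/<id>/AF_detection_result.csv
        patients/<id>/alarms.log
        patients/<id>/alarm_state.json
        patients/<id>/diagnoses.jsonl
    """

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._registry_path = self.root / "registry.json"
        if self._registry_path.exists():
            payload = json.loads(self._registry_path.read_text())
            if payload.get("format") != REGISTRY_FORMAT:
                raise ValueError(f"{self._registry_path}: unknown registry format")
            self._records = {
                pid: PatientRecord.from_json(d) for pid, d in payload["patients"].items()
            }
        else:
            self._records = {}
            self._persist()

    # -- registry -----------------------------------------------------------

    def _persist(self) -> None:
        payload = {
            "format": REGISTRY_FORMAT,
            "patients": {pid: r.to_json() for pid, r in sorted(self._records.items())},
        }
        self._registry_path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self._records

    def record(self, patient_id: str) -> PatientRecord:
        try:
            return self._records[patient_id]
        except KeyError:
            raise KeyError(f"patient {patient_id!r} is not registered") from None

    def register_patient(self, record: PatientRecord) -> None:
        """Add a patient and create their two (empty) cloud channels."""
        if record.patient_id in self._records:
            raise ValueError(f"patient {record.patient_id!r} is already registered")
        self._records[record.patient_id] = record
        pdir = self.root / "patients" / record.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        channels.write_rr_channel(RRSeries(intervals=np.array([])), pdir / f"{RR_CHANNEL}.csv")
        channels.write_result_channel(
            ProbabilityTrace([], []), pdir / f"{RESULT_CHANNEL}.csv"
        )
        self._persist()

    # -- channel access (key-gated) ----------------------------------------

    def _authorize(self, patient_id: str, channel_key: str) -> PatientRecord:
        record = self.record(patient_id)
        if channel_key != record.channel_key:
            raise AuthorizationError(f"channel key rejected for patient {patient_id!r}")
        return record

    def _pdir(self, patient_id: str) -> Path:
        return self.root / "patients" / patient_id

    def rr_channel_path(self, patient_id: str, channel_key: str) -> Path:
        self._authorize(patient_id, channel_key)
        return self._pdir(patient_id) / f"{RR_CHANNEL}.csv"

    def result_channel_path(self, patient_id: str, channel_key: str) -> Path:
        self._authorize(patient_id, channel_key)
        return self._pdir(patient_id) / f"{RESULT_CHANNEL}.csv"

    def append_rr(self, patient_id: str, channel_key: str, intervals_ms) -> None:
        """Append newly measured beats to the patient's RR channel.

        The channel is rewritten from the full interval sequence, so chunked
        uploads yield a file byte-identical to a single upload of all beats
        (interval values round-trip exactly through the CSV).
        """
        path = self.rr_channel_path(patient_id, channel_key)
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        if len(intervals_ms) == 0:
            return
        if np.min(intervals_ms) <= 0:
            raise ValueError("all RR intervals must be positive")
        try:
            existing = channels.read_rr_channel(path, patient_id=patient_id).intervals
        except channels.EmptyChannelError:
            existing = np.array([])
        combined = np.concatenate([existing, intervals_ms])
        channels.write_rr_channel(RRSeries(intervals=combined), path)

    def read_rr(self, patient_id: str, channel_key: str) -> RRSeries:
        return channels.read_rr_channel(
            self.rr_channel_path(patient_id, channel_key), patient_id=patient_id
        )

    # -- monitoring ---------------------------------------------------------

    def run_patient_monitor(
        self,
        patient_id: str,
        channel_key: str,
        model: DetectorModel,
        windowing: Optional[WindowingConfig] = None,
        rule: Optional[AlarmRule] = None,
        today: Optional[date] = None,
    ) -> MonitorOutcome:
        """One poll of the patient monitor: fetch → classify → publish → alarm.

        Re-running with no new RR data writes nothing and emits nothing
        (idempotence).  The full result channel and alarm log are rewritten
        deterministically from the complete trace, so incremental polling
        yields byte-identical files to one-shot batch processing.
        """
        record = self._authorize(patient_id, channel_key)
        wcfg = windowing or WindowingConfig(window_len=100, stride=10)
        rule = rule or AlarmRule()
        out_of_period = today is not None and not (
            record.service_start <= today <= record.service_end
        )

        rr_path = self.rr_channel_path(patient_id, channel_key)
        res_path = self.result_channel_path(patient_id, channel_key)
        try:
            series = channels.read_rr_channel(rr_path, patient_id=patient_id)
        except channels.EmptyChannelError:
            return MonitorOutcome(patient_id, 0, 0, [], False, out_of_period)
        if len(series) < wcfg.window_len:
            return MonitorOutcome(patient_id, 0, 0, [], False, out_of_period)

        n_windows = len(make_windows(series, wcfg))
        existing = channels.read_result_channel(res_path)
        if n_windows <= len(existing):
            return MonitorOutcome(patient_id, n_windows, 0, [], False, out_of_period)

        trace = predict_trace(model, series, wcfg)
        channels.write_result_channel(trace, res_path, epoch=series.t_origin)

        events = scan_trace(trace, rule)
        state_path = self._pdir(patient_id) / "alarm_state.json"
        dispatched: List[float] = (
            json.loads(state_path.read_text()) if state_path.exists() else []
        )
        messages = []
        new_messages = []
        for ev in events:
            ev.patient_id = patient_id
            msg = dispatch(ev, record, evidence_channel=RESULT_CHANNEL)
            messages.append(msg)
            if ev.run_start not in dispatched:
                new_messages.append(msg)
                dispatched.append(ev.run_start)
        (self._pdir(patient_id) / "alarms.log").write_text(format_alarm_log(messages))
        state_path.write_text(json.dumps(sorted(dispatched)))
        return MonitorOutcome(
            patient_id, n_windows, n_windows - len(existing), new_messages, True,
            out_of_period,
        )

    # -- physician review ---------------------------------------------------

    def physician_report(
        self, patient_id: str, channel_key: str, roi: RegionOfInterest
    ) -> PhysicianReport:
        """Evidence bundle for a review session over a region of interest."""
        record = self._authorize(patient_id, channel_key)
        series = channels.read_rr_channel(
            self.rr_channel_path(patient_id, channel_key), patient_id=patient_id
        )
        trace = channels.read_result_channel(
            self.result_channel_path(patient_id, channel_key)
        )
        if len(trace) == 0:
            raise ValueError(
                f"patient {patient_id!r} has no detection results yet; run the monitor first"
            )
        roi_series = extract_region(series, roi)
        return PhysicianReport(
            patient_id=patient_id,
            trace=trace,
            max_probability=float(np.max(trace.probabilities)),
            fraction_above_half=float(np.mean(trace.probabilities > 0.5)),
            roi=roi,
            roi_series=roi_series,
            roi_colours=probability_colour_map(trace, roi_series),
            biomarkers=compute_biomarkers(roi_series),
        )

    def record_diagnosis(self, diagnosis: Diagnosis) -> None:
        """Append a physician's accept/reject decision to the audit log.

        A rejected AF call never deregisters the patient: monitoring simply
        continues.  The log doubles as ground truth for future retraining.
        """
        self.record(diagnosis.patient_id)
        if diagnosis.outcome not in (AF_CONFIRMED, AF_REJECTED):
            raise ValueError(f"unknown diagnosis outcome {diagnosis.outcome!r}")
        path = self._pdir(diagnosis.patient_id) / "diagnoses.jsonl"
        with open(path, "a") as fh:
            fh.write(json.dumps({
                "patient_id": diagnosis.patient_id,
                "physician_id": diagnosis.physician_id,
                "outcome": diagnosis.outcome,
                "time": diagnosis.time,
                "roi": [diagnosis.roi_start, diagnosis.roi_end],
            }) + "\n")

    def diagnoses(self, patient_id: str) -> List[Diagnosis]:
        self.record(patient_id)
        path = self._pdir(patient_id) / "diagnoses.jsonl"
        out: List[Diagnosis] = []
        if path.exists():
            for line in path.read_text().splitlines():
                d = json.loads(line)
                out.append(Diagnosis(
                    patient_id=d["patient_id"], physician_id=d["physician_id"],
                    outcome=d["outcome"], time=d["time"],
                    roi_start=d["roi"][0], roi_end=d["roi"][1],
                ))
        return out

    # -- feedback -----------------------------------------------------------

    def feedback_status(
        self, patient_id: str, channel_key: str, now: float
    ) -> FeedbackStatus:
        """Traffic-light status at simulated time ``now`` (seconds).

        * red — the physician has confirmed AF (latest diagnosis);
        * orange — an alarm awaits physician review, or the data stream has
          been silent for longer than the interruption threshold;
        * green — data flowing, no unreviewed alarm, no confirmed AF.
        """
        self._authorize(patient_id, channel_key)
        diags = self.diagnoses(patient_id)
        latest = diags[-1] if diags else None
        if latest is not None and latest.outcome == AF_CONFIRMED:
            return FeedbackStatus(RED, "AF confirmed by physician — see your physician immediately", now)

        state_path = self._pdir(patient_id) / "alarm_state.json"
        dispatched = json.loads(state_path.read_text()) if state_path.exists() else []
        last_review = latest.time if latest is not None else -np.inf
        unreviewed = [t for t in dispatched if t > last_review]
        if unreviewed:
            return FeedbackStatus(
                ORANGE, "AF alarm awaiting physician review — take precautionary action", now
            )

        try:
            series = channels.read_rr_channel(
                self.rr_channel_path(patient_id, channel_key), patient_id=patient_id
            )
            last_beat = float(series.beat_times[-1])
        except channels.EmptyChannelError:
            last_beat = -np.inf
        if now - last_beat > DATA_INTERRUPTION_S:
            return FeedbackStatus(ORANGE, "signal interruption — check the sensor", now)
        return FeedbackStatus(GREEN, "all is well", now)
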