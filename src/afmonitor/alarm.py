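"""Sustained-probability alarm rule and dispatch.

An AF event is raised when the estimated AF probability stays strictly above
a threshold (default 0.5) for at least a minimum duration (default 30 s).
The probability trace is sampled, so a "run" is a maximal stretch of
consecutive super-threshold samples with no gap larger than the configured
gap limit; its duration is measured from the first to the last sample of the
run.  The rule is deliberately configurable: the 0.5 / 30 s defaults follow
ambulatory-monitoring convention and have not been clinically validated as
an alarm criterion.

Detected events are dispatched as alarm messages to the patient's assigned
physician; the service contract requires dispatch within 5 minutes of
detection, which is asserted on the (simulated) timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np

from .channels import ProbabilityTrace

__all__ = [
    "AlarmRule",
    "AlarmEvent",
    "AlarmMessage",
    "scan_trace",
    "dispatch",
    "StreamScanner",
    "format_alarm_log",
    "DISPATCH_LATENCY_LIMIT_S",
]

#: Alarm messages must reach the physician within 5 minutes of detection.
DISPATCH_LATENCY_LIMIT_S = 300.0


@dataclass(frozen=True)
class AlarmRule:
    """Sustained-threshold rule: probability strictly above ``threshold``
    for at least ``min_duration`` seconds.

    ``max_gap`` bounds the spacing between consecutive samples inside a run;
    a larger gap breaks the run so that missing data never silently counts
    as super-threshold.
    """

    threshold: float = 0.5
    min_duration: float = 30.0
    max_gap: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


@dataclass
class AlarmEvent:
    """One sustained super-threshold run that satisfied the alarm rule."""

    run_start: float
    detection_time: float
    run_end: float
    max_probability: float
    patient_id: Optional[str] = None

    def key(self) -> float:
        """Stable identity of the event within a trace: its run start."""
        return self.run_start


@dataclass
class AlarmMessage:
    """Alarm notification to the assigned physician, with evidence pointer."""

    patient_id: str
    physician_id: str
    detection_time: float
    dispatch_time: float
    evidence_channel: str
    evidence_start: float
    evidence_end: float
    latency_violation: bool = field(default=False)

    @property
    def latency(self) -> float:
        return self.dispatch_time - self.detection_time


def scan_trace(trace: ProbabilityTrace, rule: AlarmRule) -> List[AlarmEvent]:
    """Find every maximal super-threshold run satisfying the alarm rule.

    Runs are broken by any sample at or below the threshold (strict ">" —
    a probability of exactly 0.5 under the default rule does not count) and
    by inter-sample gaps exceeding ``rule.max_gap``.  A run qualifies when
    its last sample is at least ``min_duration`` after its first;
    ``detection_time`` is ``run_start + min_duration``, the earliest instant
    at which the rule holds.
    """
    t = np.asarray(trace.times, dtype=float)
    p = np.asarray(trace.probabilities, dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("trace times must be strictly increasing")

    events: List[AlarmEvent] = []
    run_start_i: Optional[int] = None
    prev_t = None
    for i in range(len(t)):
        gap_broken = (
            run_start_i is not None and prev_t is not None and t[i] - prev_t > rule.max_gap
        )
        if gap_broken:
            _close_run(events, t, p, run_start_i, i - 1, rule)
            run_start_i = None
        if p[i] > rule.threshold:
            if run_start_i is None:
                run_start_i = i
        else:
            if run_start_i is not None:
                _close_run(events, t, p, run_start_i, i - 1, rule)
                run_start_i = None
        prev_t = t[i]
    if run_start_i is not None:
        _close_run(events, t, p, run_start_i, len(t) - 1, rule)
    return events


def _close_run(events, t, p, start_i, end_i, rule) -> None:
    if t[end_i] - t[start_i] >= rule.min_duration:
        events.append(
            AlarmEvent(
                run_start=float(t[start_i]),
                detection_time=float(t[start_i]) + rule.min_duration,
                run_end=float(t[end_i]),
                max_probability=float(np.max(p[start_i : end_i + 1])),
            )
        )


def dispatch(
    event: AlarmEvent,
    record,
    *,
    dispatch_time: Optional[float] = None,
    evidence_channel: str = "AF_detection_result",
    evidence_lead_s: float = 60.0,
) -> AlarmMessage:
    """Build the alarm message for an event, addressed to the assigned
    physician of the patient's registry record.

    ``dispatch_time`` defaults to the detection time (simulated immediate
    dispatch).  If the supplied dispatch time misses the 5-minute latency
    contract, the message is still produced but flagged.
    """
    physician = getattr(record, "assigned_physician", None)
    if not physician:
        raise ValueError(f"patient {getattr(record, 'patient_id', '?')} has no assigned physician")
    when = event.detection_time if dispatch_time is None else float(dispatch_time)
    violation = when - event.detection_time > DISPATCH_LATENCY_LIMIT_S
    return AlarmMessage(
        patient_id=record.patient_id,
        physician_id=physician,
        detection_time=event.detection_time,
        dispatch_time=when,
        evidence_channel=evidence_channel,
        evidence_start=event.run_start - evidence_lead_s,
        evidence_end=event.run_end,
        latency_violation=violation,
    )


class StreamScanner:
    """Incremental alarm scanning over a growing probability trace.

    Samples are appended in chronological chunks (as a polling monitor would
    deliver them).  The scanner maintains only the open run's state, emits an
    event exactly once when the run first satisfies the rule, and keeps the
    open event's ``run_end`` current so that, after :meth:`finalize`, the
    accumulated events equal a batch :func:`scan_trace` of the full trace.
    """

    def __init__(self, rule: AlarmRule):
        self.rule = rule
        self._events: List[AlarmEvent] = []
        self._open_event: Optional[AlarmEvent] = None
        self._run_start: Optional[float] = None
        self._run_end: Optional[float] = None
        self._run_max_p: float = 0.0
        self._last_t: Optional[float] = None

    def feed(self, times: Iterable[float], probabilities: Iterable[float]) -> List[AlarmEvent]:
        """Append new samples; returns events newly *detected* by this chunk."""
        new: List[AlarmEvent] = []
        for t, p in zip(times, probabilities):
            t, p = float(t), float(p)
            if self._last_t is not None and t <= self._last_t:
                raise ValueError(f"stream time went backwards: {t} after {self._last_t}")
            if (
                self._run_start is not None
                and self._last_t is not None
                and t - self._last_t > self.rule.max_gap
            ):
                self._close_run()
            if p > self.rule.threshold:
                if self._run_start is None:
                    self._run_start = t
                    self._run_max_p = p
                self._run_end = t
                self._run_max_p = max(self._run_max_p, p)
                if self._open_event is None and t - self._run_start >= self.rule.min_duration:
                    self._open_event = AlarmEvent(
                        run_start=self._run_start,
                        detection_time=self._run_start + self.rule.min_duration,
                        run_end=t,
                        max_probability=self._run_max_p,
                    )
                    self._events.append(self._open_event)
                    new.append(self._open_event)
                elif self._open_event is not None:
                    self._open_event.run_end = t
                    self._open_event.max_probability = self._run_max_p
            else:
                self._close_run()
            self._last_t = t
        return new

    def _close_run(self) -> None:
        self._run_start = None
        self._run_end = None
        self._run_max_p = 0.0
        self._open_event = None

    def finalize(self) -> List[AlarmEvent]:
        """All events detected so far (open runs already carry their current
        end time); equals ``scan_trace`` over everything fed."""
        return list(self._events)


def format_alarm_log(messages: List[AlarmMessage]) -> str:
    """Render messages as a deterministic line-delimited log."""
    lines = []
    for m in sorted(messages, key=lambda m: (m.detection_time, m.patient_id)):
        lines.append(
            f"patient={m.patient_id} physician={m.physician_id} "
            f"detection_time={m.detection_time!r} dispatch_time={m.dispatch_time!r} "
            f"evidence={m.evidence_channel}[{m.evidence_start!r},{m.evidence_end!r}] "
            f"latency_ok={not m.latency_violation}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
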