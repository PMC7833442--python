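"""Synthetic RR-interval rhythm generation.

Produces beat-to-beat interval series for two rhythm regimes:

* **NSR** (normal sinus rhythm) — a stable mean interval with a sinusoidal
  respiratory-modulation term (respiratory sinus arrhythmia) plus small
  Gaussian noise.  Variability is modest and serially structured.
* **AF** (atrial fibrillation) — "irregularly irregular" intervals, modelled
  as a truncated first-order autoregressive process with a low lag-1
  correlation and a large stationary standard deviation, so successive
  intervals are nearly independent and widely dispersed.

These are synthetic conventions: the generator is a stand-in for patient
measurements so the downstream detector, alarm and biomarker stages can be
exercised without any external recordings.  The default parameter values are
plausible physiological magnitudes, not estimates from any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NSR",
    "AF",
    "RhythmParams",
    "EpisodeSchedule",
    "RRSeries",
    "generate_segment",
    "generate_recording",
]

NSR = "NSR"
AF = "AF"

#: Hard physiological floor on a beat-to-beat interval, ms.  Draws below the
#: floor are rejected and resampled (an RR interval of < 250 ms would imply a
#: sustained rate above 240 bpm, outside the regimes modelled here).
INTERVAL_FLOOR_MS = 250.0


@dataclass(frozen=True)
class RhythmParams:
    """Parameters of the two-regime rhythm model.

    All interval-scale quantities are in milliseconds; periods in seconds.
    ``af_lag1_corr`` is the lag-1 autocorrelation of the AF interval process
    (near zero = irregularly irregular).  ``seed`` fully determines every
    stochastic draw of a generation call.
    """

    nsr_mean_rr: float = 850.0
    nsr_sd: float = 30.0
    nsr_resp_period: float = 4.0
    nsr_resp_amp: float = 25.0
    af_mean_rr: float = 700.0
    af_sd: float = 120.0
    af_lag1_corr: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nsr_mean_rr", "nsr_resp_period", "af_mean_rr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("nsr_sd", "nsr_resp_amp", "af_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.af_lag1_corr < 1.0:
            raise ValueError("af_lag1_corr must lie in [0, 1)")
        if self.nsr_mean_rr <= INTERVAL_FLOOR_MS or self.af_mean_rr <= INTERVAL_FLOOR_MS:
            raise ValueError(
                f"mean RR must exceed the {INTERVAL_FLOOR_MS} ms physiological floor"
            )

    def with_seed(self, seed: int) -> "RhythmParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class EpisodeSchedule:
    """Ordered rhythm segments of a recording: ``[(label, duration_s), ...]``.

    Segments are contiguous; paroxysmal AF is expressed as AF segments
    interleaved with NSR.
    """

    segments: tuple[tuple[str, float], ...]

    def __init__(self, segments: Sequence[tuple[str, float]]) -> None:
        segments = tuple((str(lab), float(dur)) for lab, dur in segments)
        if not segments:
            raise ValueError("schedule must contain at least one segment")
        for lab, dur in segments:
            if lab not in (NSR, AF):
                raise ValueError(f"unknown rhythm label {lab!r}")
            if dur <= 0:
                raise ValueError(f"segment durations must be positive, got {dur}")
        object.__setattr__(self, "segments", segments)

    @property
    def total_duration(self) -> float:
        return sum(dur for _, dur in self.segments)


@dataclass
class RRSeries:
    """A beat-to-beat interval sequence with derived beat times.

    ``intervals`` are in ms; ``beat_times`` in seconds are the cumulative sum
    of intervals from the series origin (``t_origin``, default 0), so beat
    ``i`` occurs at the *end* of interval ``i``.  ``labels`` carry per-beat
    rhythm ground truth when known (synthetic data); real recordings may omit
    them.
    """

    intervals: np.ndarray
    labels: Optional[np.ndarray] = None
    patient_id: Optional[str] = None
    t_origin: float = 0.0
    beat_times: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if len(self.intervals) and np.min(self.intervals) <= 0:
            raise ValueError("all RR intervals must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != self.intervals.shape:
                raise ValueError("labels must match intervals in length")
        self.beat_times = self.t_origin + np.cumsum(self.intervals) / 1000.0

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration(self) -> float:
        """Span in seconds from the origin to the last beat."""
        return 0.0 if len(self) == 0 else float(self.beat_times[-1] - self.t_origin)

    def slice_beats(self, start: int, stop: int) -> "RRSeries":
        """Sub-series of beats ``start:stop`` keeping absolute beat times."""
        origin = self.t_origin if start == 0 else float(self.beat_times[start - 1])
        return RRSeries(
            intervals=self.intervals[start:stop].copy(),
            labels=None if self.labels is None else self.labels[start:stop].copy(),
            patient_id=self.patient_id,
            t_origin=origin,
        )


def _draw_intervals(
    rng: np.random.Generator,
    rhythm: str,
    params: RhythmParams,
    duration: float,
    t0: float,
    prev_af_interval: Optional[float],
) -> tuple[np.ndarray, Optional[float]]:
    """Draw intervals until cumulative time first reaches ``duration`` s.

    Returns the interval array (ms) and, for AF, the last interval so an
    adjacent AF segment can continue the autoregressive state.
    """
    intervals: list[float] = []
    t = 0.0
    duration_ms = duration * 1000.0

    if rhythm == NSR:
        while t < duration_ms:
            beat_onset_s = t0 + t / 1000.0
            modulation = params.nsr_resp_amp * np.sin(
                2.0 * np.pi * beat_onset_s / params.nsr_resp_period
            )
            x = params.nsr_mean_rr + modulation + rng.normal(0.0, params.nsr_sd)
            while x < INTERVAL_FLOOR_MS:
                x = params.nsr_mean_rr + modulation + rng.normal(0.0, params.nsr_sd)
            intervals.append(x)
            t += x
        return np.asarray(intervals), None

    # AF: stationary AR(1) in the interval domain, innovations scaled so the
    # marginal sd equals af_sd, rejected below the physiological floor.
    phi = params.af_lag1_corr
    innov_sd = params.af_sd * np.sqrt(1.0 - phi * phi)
    x_prev = prev_af_interval if prev_af_interval is not None else None
    while t < duration_ms:
        if x_prev is None:
            x = params.af_mean_rr + rng.normal(0.0, params.af_sd)
            while x < INTERVAL_FLOOR_MS:
                x = params.af_mean_rr + rng.normal(0.0, params.af_sd)
        else:
            x = params.af_mean_rr + phi * (x_prev - params.af_mean_rr) + rng.normal(0.0, innov_sd)
            while x < INTERVAL_FLOOR_MS:
                x = (
                    params.af_mean_rr
                    + phi * (x_prev - params.af_mean_rr)
                    + rng.normal(0.0, innov_sd)
                )
        intervals.append(x)
        x_prev = x
        t += x
    return np.asarray(intervals), x_prev


def generate_segment(
    params: RhythmParams,
    rhythm: str,
    duration: float,
    *,
    patient_id: Optional[str] = None,
) -> RRSeries:
    """Generate a single-rhythm segment of ``duration`` seconds.

    Beats are emitted until the cumulative interval time first reaches the
    requested duration, so the realised span may overshoot by at most one
    interval.  In the deterministic limit (zero noise, zero modulation) an
    NSR segment of 60 s at mean RR 1000 ms is exactly 60 beats of 1000 ms.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if rhythm not in (NSR, AF):
        raise ValueError(f"unknown rhythm label {rhythm!r}")
    rng = np.random.default_rng(params.seed)
    intervals, _ = _draw_intervals(rng, rhythm, params, duration, 0.0, None)
    labels = np.asarray([rhythm] * len(intervals), dtype=object)
    return RRSeries(intervals=intervals, labels=labels, patient_id=patient_id)


def generate_recording(
    params: RhythmParams,
    schedule: EpisodeSchedule,
    *,
    patient_id: Optional[str] = None,
) -> RRSeries:
    """Generate a multi-segment recording following an episode schedule.

    Segments are generated back to back with a continuous time axis from one
    random generator seeded by ``params.seed``.  Each beat is labelled with
    the rhythm of the segment in which its onset falls; because a segment
    runs until its cumulative time reaches the scheduled duration, the
    realised segment boundary is the end time of its final beat, and the next
    segment begins there.  The AR(1) state of the AF process is reset at
    every segment boundary (episodes are independent events).
    """
    rng = np.random.default_rng(params.seed)
    all_intervals: list[np.ndarray] = []
    all_labels: list[str] = []
    t = 0.0
    for rhythm, duration in schedule.segments:
        segment, _ = _draw_intervals(rng, rhythm, params, duration, t, None)
        all_intervals.append(segment)
        all_labels.extend([rhythm] * len(segment))
        t += float(np.sum(segment)) / 1000.0
    return RRSeries(
        intervals=np.concatenate(all_intervals),
        labels=np.asarray(all_labels, dtype=object),
        patient_id=patient_id,
    )


def parse_schedule_file(path) -> EpisodeSchedule:
    """Read a two-column text schedule: ``label duration_s`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    segments = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'label duration_s', got {raw!r}")
            segments.append((parts[0], float(parts[1])))
    return EpisodeSchedule(segments)
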