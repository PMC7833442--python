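"""Channel file I/O emulating the cloud storage of the telemonitoring service.

Each patient has two channels: ``RR_interval_data`` holding the heart-rate
measurements (one RR interval per row) and ``AF_detection_result`` holding
the classifier output (one AF probability per row).  Here a channel is a
plain CSV file

    # epoch=<seconds>
    timestamp,value

with timestamps in seconds since the per-file epoch and values in ms (RR
channels) or in [0, 1] (result channels).  Readers validate rather than
clamp: out-of-range rows are a hard error that names the offending lines.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np

from .rhythm import RRSeries

__all__ = [
    "ChannelFormatError",
    "EmptyChannelError",
    "read_rr_channel",
    "write_rr_channel",
    "read_result_channel",
    "write_result_channel",
    "ProbabilityTrace",
    "read_wfdb_rr",
]

RR_CHANNEL = "RR_interval_data"
RESULT_CHANNEL = "AF_detection_result"

_HEADER = "timestamp,value"


class ChannelFormatError(ValueError):
    """A channel file violates the format contract; carries offending lines."""

    def __init__(self, path, problems: list[str]):
        self.path = str(path)
        self.problems = problems
        detail = "; ".join(problems[:10])
        if len(problems) > 10:
            detail += f"; ... ({len(problems)} problems total)"
        super().__init__(f"{path}: {detail}")


class EmptyChannelError(ValueError):
    pass


class ProbabilityTrace:
    """Time-indexed AF-probability estimates, one entry per analysis window.

    ``times`` (s, strictly increasing) stamp each probability at the final
    beat of the window that produced it; ``probabilities`` lie in [0, 1].
    """

    __slots__ = ("times", "probabilities")

    def __init__(self, times, probabilities):
        self.times = np.asarray(times, dtype=float)
        self.probabilities = np.asarray(probabilities, dtype=float)
        if self.times.shape != self.probabilities.shape or self.times.ndim != 1:
            raise ValueError("times and probabilities must be 1-D and equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if len(self.probabilities) and (
            np.min(self.probabilities) < 0 or np.max(self.probabilities) > 1
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProbabilityTrace)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.probabilities, other.probabilities)
        )

    def __repr__(self) -> str:
        return f"ProbabilityTrace(n={len(self)})"


def _fmt(x: float) -> str:
    # repr of a float round-trips exactly; fixed formatting keeps files
    # byte-deterministic for a given series.
    return repr(float(x))


def _parse_channel(path) -> tuple[float, np.ndarray, np.ndarray, list[int]]:
    path = Path(path)
    epoch = 0.0
    times: list[float] = []
    values: list[float] = []
    linenos: list[int] = []
    problems: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    if body_start < len(lines) and lines[body_start].startswith("#"):
        comment = lines[body_start].lstrip("#").strip()
        if comment.startswith("epoch="):
            epoch = float(comment.split("=", 1)[1])
        body_start += 1
    if body_start >= len(lines) or lines[body_start].strip() != _HEADER:
        raise ChannelFormatError(path, [f"line {body_start + 1}: missing '{_HEADER}' header"])
    for lineno, raw in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            problems.append(f"line {lineno}: expected 2 columns, got {len(parts)}")
            continue
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError:
            problems.append(f"line {lineno}: non-numeric field in {raw!r}")
            continue
        if not (math.isfinite(t) and math.isfinite(v)):
            problems.append(f"line {lineno}: non-finite value in {raw!r}")
            continue
        if times and t < times[-1]:
            problems.append(f"line {lineno}: timestamp {t} decreases")
            continue
        times.append(t)
        values.append(v)
        linenos.append(lineno)
    if problems:
        raise ChannelFormatError(path, problems)
    return epoch, np.asarray(times), np.asarray(values), linenos


def read_rr_channel(path, *, patient_id: Optional[str] = None) -> RRSeries:
    """Read an ``RR_interval_data`` channel file into an :class:`RRSeries`.

    Rows with non-positive intervals are a hard error reporting their line
    numbers; an empty (header-only) file raises :class:`EmptyChannelError`.
    """
    epoch, times, values, linenos = _parse_channel(path)
    if len(values) == 0:
        raise EmptyChannelError(f"{path}: RR channel holds no beats")
    bad = np.nonzero(values <= 0)[0]
    if len(bad):
        problems = [
            f"line {linenos[i]}: non-positive RR interval {values[i]} ms" for i in bad
        ]
        raise ChannelFormatError(path, problems)
    return RRSeries(intervals=values, patient_id=patient_id, t_origin=epoch)


def write_rr_channel(series: RRSeries, path) -> None:
    """Write an RR series as a channel CSV (byte-deterministic).

    Timestamps are the beat times in seconds relative to the series origin,
    which is recorded as the file epoch; values are intervals in ms.
    """
    lines = [f"# epoch={_fmt(series.t_origin)}", _HEADER]
    rel_times = series.beat_times - series.t_origin
    for t, v in zip(rel_times, series.intervals):
        lines.append(f"{_fmt(t)},{_fmt(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_result_channel(path) -> ProbabilityTrace:
    """Read an ``AF_detection_result`` channel into a probability trace."""
    epoch, times, values, linenos = _parse_channel(path)
    bad = np.nonzero((values < 0) | (values > 1))[0]
    if len(bad):
        problems = [
            f"line {linenos[i]}: probability {values[i]} outside [0, 1]" for i in bad
        ]
        raise ChannelFormatError(path, problems)
    return ProbabilityTrace(times=epoch + times, probabilities=values)


def write_result_channel(trace: ProbabilityTrace, path, *, epoch: float = 0.0) -> None:
    """Write a probability trace as a channel CSV (byte-deterministic)."""
    lines = [f"# epoch={_fmt(epoch)}", _HEADER]
    for t, p in zip(trace.times, trace.probabilities):
        lines.append(f"{_fmt(t - epoch)},{_fmt(p)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_wfdb_rr(record: str, annotator: str = "atr") -> RRSeries:
    """Optional adapter: RR intervals from PhysioNet beat annotations.

    Requires the ``wfdb`` package and a locally downloaded record; provided
    for users who want to run the detector on AFDB-style data.  Not used by
    any test.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading PhysioNet annotations requires the optional 'wfdb' package"
        ) from exc
    ann = wfdb.rdann(record, annotator)  # pragma: no cover
    beat_samples = np.asarray(ann.sample, dtype=float)  # pragma: no cover
    intervals_ms = np.diff(beat_samples) / ann.fs * 1000.0  # pragma: no cover
    return RRSeries(intervals=intervals_ms)  # pragma: no cover
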