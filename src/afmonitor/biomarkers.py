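"""Time-domain HRV digital biomarkers for physician review.

Given a region of interest (ROI) of the RR trace, this module computes the
standard time-domain heart-rate-variability panel — mean/median RR, SDNN,
SDSD, RMSSD, NN50, pNN50, mean HR and the Poincaré dispersions SD1/SD2 —
which a physician uses as independent evidence when accepting or rejecting
the detector's AF call.  AF typically shows markedly elevated RMSSD/pNN50
relative to sinus rhythm because successive intervals are nearly
uncorrelated.

Conventions: standard deviations use the population (1/n) form; NN50 counts
successive-difference magnitudes *strictly* greater than 50 ms; SD1 is
SDSD/√2 and SD2 is √(2·SDNN² − SD1²) floored at zero.  No ectopic-beat
filtering is applied before the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import ProbabilityTrace
from .rhythm import RRSeries

__all__ = [
    "RegionOfInterest",
    "BiomarkerSet",
    "EmptyRegionError",
    "extract_region",
    "compute_biomarkers",
    "probability_colour_map",
    "COLOUR_LOW",
    "COLOUR_MID",
    "COLOUR_HIGH",
    "COLOUR_UNSCORED",
]

COLOUR_UNSCORED = "unscored"
COLOUR_LOW = "low"     # p < 0.25
COLOUR_MID = "mid"     # 0.25 <= p <= 0.75
COLOUR_HIGH = "high"   # p > 0.75


class EmptyRegionError(ValueError):
    pass


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open time window [start, end) in seconds on the beat-time axis."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"ROI end ({self.end}) must exceed start ({self.start})")


@dataclass(frozen=True)
class BiomarkerSet:
    """Time-domain HRV statistics over one region of interest.

    Units: intervals in ms, heart rate in bpm, pNN50 in percent of
    successive differences.
    """

    n_beats: int
    mean_rr: float
    median_rr: float
    sdnn: float
    sdsd: float
    rmssd: float
    nn50: int
    pnn50: float
    mean_hr: float
    sd1: float
    sd2: float

    def as_dict(self) -> dict:
        return {
            "n_beats": self.n_beats, "mean_rr": self.mean_rr,
            "median_rr": self.median_rr, "sdnn": self.sdnn, "sdsd": self.sdsd,
            "rmssd": self.rmssd, "nn50": self.nn50, "pnn50": self.pnn50,
            "mean_hr": self.mean_hr, "sd1": self.sd1, "sd2": self.sd2,
        }

    def table(self) -> str:
        rows = [
            ("beats", f"{self.n_beats}", ""),
            ("mean RR", f"{self.mean_rr:.1f}", "ms"),
            ("median RR", f"{self.median_rr:.1f}", "ms"),
            ("SDNN", f"{self.sdnn:.1f}", "ms"),
            ("SDSD", f"{self.sdsd:.1f}", "ms"),
            ("RMSSD", f"{self.rmssd:.1f}", "ms"),
            ("NN50", f"{self.nn50}", "beats"),
            ("pNN50", f"{self.pnn50:.1f}", "%"),
            ("mean HR", f"{self.mean_hr:.1f}", "bpm"),
            ("Poincare SD1", f"{self.sd1:.1f}", "ms"),
            ("Poincare SD2", f"{self.sd2:.1f}", "ms"),
        ]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {val:>8} {unit}" for name, val, unit in rows)


def extract_region(series: RRSeries, roi: RegionOfInterest) -> RRSeries:
    """Beats whose beat time falls in [roi.start, roi.end), order preserved."""
    mask = (series.beat_times >= roi.start) & (series.beat_times < roi.end)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise EmptyRegionError(
            f"region [{roi.start}, {roi.end}) s contains no beats "
            f"(series spans {series.t_origin}..{series.beat_times[-1] if len(series) else series.t_origin} s)"
        )
    start, stop = int(idx[0]), int(idx[-1]) + 1
    return series.slice_beats(start, stop)


def compute_biomarkers(series: RRSeries) -> BiomarkerSet:
    """Compute the time-domain panel over a series (needs ≥ 2 beats)."""
    x = np.asarray(series.intervals, dtype=float)
    if len(x) < 2:
        raise ValueError("biomarkers need at least 2 beats (1 successive difference)")
    d = np.diff(x)
    mean_rr = float(np.mean(x))
    sdnn = float(np.std(x))          # population form
    sdsd = float(np.std(d))
    rmssd = float(np.sqrt(np.mean(d**2)))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    sd1 = sdsd / np.sqrt(2.0)
    sd2 = float(np.sqrt(max(2.0 * sdnn**2 - sd1**2, 0.0)))
    return BiomarkerSet(
        n_beats=len(x),
        mean_rr=mean_rr,
        median_rr=float(np.median(x)),
        sdnn=sdnn,
        sdsd=sdsd,
        rmssd=rmssd,
        nn50=nn50,
        pnn50=100.0 * nn50 / len(d),
        mean_hr=60000.0 / mean_rr,
        sd1=float(sd1),
        sd2=sd2,
    )


def probability_colour_map(trace: ProbabilityTrace, series: RRSeries) -> np.ndarray:
    """Colour class per beat from the most recent AF probability.

    Each beat takes the probability of the latest analysis window ending at
    or before the beat's time; beats preceding the first window are
    "unscored".  Classes: low (p < 0.25), mid (0.25–0.75), high (p > 0.75).
    """
    colours = np.full(len(series), COLOUR_UNSCORED, dtype=object)
    if len(trace) == 0 or len(series) == 0:
        return colours
    idx = np.searchsorted(trace.times, series.beat_times, side="right") - 1
    scored = idx >= 0
    p = trace.probabilities[np.clip(idx, 0, None)]
    colours[scored & (p < 0.25)] = COLOUR_LOW
    colours[scored & (p >= 0.25) & (p <= 0.75)] = COLOUR_MID
    colours[scored & (p > 0.75)] = COLOUR_HIGH
    return colours
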