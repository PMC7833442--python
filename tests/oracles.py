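"""Independent brute-force oracles used by the tests.

These are deliberately naive re-implementations, kept free of any code from
the package's own computation paths: plain loops and direct formulas.
"""

import math


def naive_biomarkers(intervals):
    """Direct-formula HRV panel over a list of intervals (ms)."""
    n = len(intervals)
    assert n >= 2
    mean_rr = sum(intervals) / n
    var = sum((x - mean_rr) ** 2 for x in intervals) / n
    sdnn = math.sqrt(var)
    diffs = [intervals[i + 1] - intervals[i] for i in range(n - 1)]
    dmean = sum(diffs) / len(diffs)
    sdsd = math.sqrt(sum((d - dmean) ** 2 for d in diffs) / len(diffs))
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    nn50 = sum(1 for d in diffs if abs(d) > 50.0)
    pnn50 = 100.0 * nn50 / len(diffs)
    srt = sorted(intervals)
    mid = n // 2
    median = srt[mid] if n % 2 else (srt[mid - 1] + srt[mid]) / 2.0
    sd1 = sdsd / math.sqrt(2.0)
    sd2 = math.sqrt(max(2.0 * sdnn**2 - sd1**2, 0.0))
    return {
        "n_beats": n,
        "mean_rr": mean_rr,
        "median_rr": median,
        "sdnn": sdnn,
        "sdsd": sdsd,
        "rmssd": rmssd,
        "nn50": nn50,
        "pnn50": pnn50,
        "mean_hr": 60000.0 / mean_rr,
        "sd1": sd1,
        "sd2": sd2,
    }


def bruteforce_alarm_runs(times, probs, threshold, min_duration, max_gap):
    """Enumerate every maximal super-threshold run by direct candidate check.

    A run is a contiguous index range whose samples all exceed the threshold
    with no inter-sample gap above max_gap, not extendable on either side.
    Every candidate start index is examined and extended sample by sample.
    Returns (run_start, detection_time, run_end, max_probability) tuples for
    runs spanning at least min_duration.
    """
    n = len(times)
    good = [p > threshold for p in probs]
    linked = [times[k + 1] - times[k] <= max_gap for k in range(n - 1)]

    events = []
    for i in range(n):
        if not good[i]:
            continue
        if i > 0 and good[i - 1] and linked[i - 1]:
            continue  # extendable to the left: not a maximal-run start
        j = i
        while j + 1 < n and good[j + 1] and linked[j]:
            j += 1
        if times[j] - times[i] >= min_duration:
            events.append(
                (times[i], times[i] + min_duration, times[j], max(probs[i : j + 1]))
            )
    return sorted(events)
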