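"""Scan a probability trace with the sustained-threshold alarm rule.

Constructs a trace that rises above 0.5 for five minutes in the middle of an
otherwise quiet hour, scans it with the default rule (p > 0.5 sustained for
30 s) and prints the resulting alarm event.  The detection time is the run
start plus the 30-s minimum duration — the earliest instant the rule holds.
"""

import numpy as np

from afmonitor import AlarmRule, ProbabilityTrace, scan_trace

times = np.arange(0.0, 3600.0, 8.0)          # one sample every 8 s
probs = np.full_like(times, 0.08)
probs[(times >= 1800) & (times < 2100)] = 0.92  # 5-minute AF episode

events = scan_trace(ProbabilityTrace(times, probs), AlarmRule())
for ev in events:
    print(f"AF event: run {ev.run_start:.0f}-{ev.run_end:.0f} s "
          f"(max p={ev.max_probability:.2f}), detected at {ev.detection_time:.0f} s")
print(f"{len(events)} event(s); detection lag after onset = "
      f"{events[0].detection_time - 1800:.0f} s")
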