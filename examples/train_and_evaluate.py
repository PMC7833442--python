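"""Train the detector on a small synthetic benchmark and evaluate it.

Uses a reduced benchmark (40 + 40 recordings) so the script runs in a few
seconds; the full-size benchmark (200 + 200) is what the test suite and the
acceptance script use.  Prints hold-out accuracy, sensitivity, specificity
and PPV computed from the confusion counts.
"""

import numpy as np

from afmonitor import WindowingConfig, evaluate_holdout, make_benchmark, make_windows, train

recordings = make_benchmark(n_per_class=40, beats=120, seed=7)
wcfg = WindowingConfig(window_len=100, stride=100)
windows, labels = [], []
for rec in recordings:
    for w in make_windows(rec, wcfg):
        windows.append(w)
        labels.append(w.label)

rng = np.random.default_rng(0)
perm = rng.permutation(len(windows))
n_tr = int(0.75 * len(windows))
tr, te = perm[:n_tr], perm[n_tr:]

model = train([windows[i] for i in tr], [labels[i] for i in tr], seed=0)
report = evaluate_holdout(model, [windows[i] for i in te], [labels[i] for i in te])
print(f"trained on {len(tr)} windows "
      f"(stopped after {model.metadata['epochs_run']} epochs)")
print(f"hold-out: accuracy={report.accuracy:.3f} sensitivity={report.sensitivity:.3f} "
      f"specificity={report.specificity:.3f} ppv={report.ppv:.3f} (n={report.n})")
print("each window is 100 beats; a probability > 0.5 classifies the window as AF")
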