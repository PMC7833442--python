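"""Shared fixtures: the standard synthetic benchmark and a trained detector.

Training is expensive relative to the rest of the suite, so one model is
trained per session on a fixed split of the benchmark and reused by the
detector, service and end-to-end tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from afmonitor.detector import WindowingConfig, make_benchmark, make_windows, train

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

BENCHMARK_SEED = 7
TRAIN_SEED = 0


@pytest.fixture(scope="session")
def benchmark_windows():
    """All windows of the standard synthetic benchmark with labels.

    200 NSR-only + 200 AF-only recordings of 120 beats, one 100-beat window
    per recording (stride 100).
    """
    recordings = make_benchmark(n_per_class=200, beats=120, seed=BENCHMARK_SEED)
    wcfg = WindowingConfig(window_len=100, stride=100)
    windows, labels = [], []
    for rec in recordings:
        for w in make_windows(rec, wcfg):
            windows.append(w)
            labels.append(w.label)
    return windows, labels


@pytest.fixture(scope="session")
def split_benchmark(benchmark_windows):
    """Deterministic 75/25 train/hold-out split of the benchmark windows."""
    windows, labels = benchmark_windows
    rng = np.random.default_rng(123)
    perm = rng.permutation(len(windows))
    n_tr = int(0.75 * len(windows))
    tr, te = perm[:n_tr], perm[n_tr:]
    return (
        [windows[i] for i in tr], [labels[i] for i in tr],
        [windows[i] for i in te], [labels[i] for i in te],
    )


@pytest.fixture(scope="session")
def trained_model(split_benchmark):
    """Detector trained once on the benchmark training split."""
    tr_w, tr_l, _, _ = split_benchmark
    return train(tr_w, tr_l, seed=TRAIN_SEED)
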