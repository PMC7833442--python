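"""AF-probability estimation from RR-interval windows.

A recording is cut into fixed-length sliding windows of beats; each window is
scored by the bidirectional-LSTM classifier (:mod:`afmonitor.nn`) with a
single probability that the window is atrial fibrillation.  Probabilities are
timestamped at the window's *final* beat, so the trace is causal and can
drive the real-time alarm rule.

The module also houses the evaluation harness: stratified ten-fold
cross-validation and hold-out evaluation, both reporting accuracy,
sensitivity, specificity and positive predictive value from explicit
confusion counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .channels import ProbabilityTrace
from .rhythm import AF, NSR, RhythmParams, RRSeries, generate_segment

__all__ = [
    "WindowingConfig",
    "Window",
    "DetectorModel",
    "TrainConfig",
    "EvalReport",
    "make_windows",
    "train",
    "predict_trace",
    "crossvalidate_10fold",
    "evaluate_holdout",
    "make_benchmark",
]

#: Interval scaling applied to network inputs: ms -> s.  Absolute rate is
#: kept (no per-window standardisation) because mean rate itself carries
#: rhythm information.
INPUT_SCALE = 1.0 / 1000.0

CHECKPOINT_FORMAT = "afmonitor-detector-v1"


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window layout in beats.

    Defaults: 100-beat windows; stride 100 (non-overlapping) for training,
    while monitoring typically passes stride 10 for a denser trace.
    """

    window_len: int = 100
    stride: int = 100

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be at least 2 beats")
        if not 1 <= self.stride <= self.window_len:
            raise ValueError("stride must satisfy 1 <= stride <= window_len")


@dataclass(frozen=True)
class Window:
    """One analysis window: its intervals (ms), label and end-beat time (s)."""

    intervals: np.ndarray
    label: Optional[str]
    end_time: float


class EvalReport:
    """Classification metrics derived from explicit confusion counts.

    AF is the positive class.  All metrics are recomputed from the counts on
    access, so they are consistent with the confusion matrix by construction.
    """

    def __init__(self, tp: int, tn: int, fp: int, fn: int):
        self.tp, self.tn, self.fp, self.fn = int(tp), int(tn), int(fp), int(fn)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    def __add__(self, other: "EvalReport") -> "EvalReport":
        return EvalReport(self.tp + other.tp, self.tn + other.tn,
                          self.fp + other.fp, self.fn + other.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv,
        }

    def __repr__(self) -> str:
        return (f"EvalReport(acc={self.accuracy:.4f} sen={self.sensitivity:.4f} "
                f"spe={self.specificity:.4f} ppv={self.ppv:.4f} n={self.n})")


@dataclass
class TrainConfig:
    """Desk-scale training hyperparameters."""

    hidden: int = 32
    lr: float = 3e-3
    batch_size: int = 64
    max_epochs: int = 50
    val_fraction: float = 0.15
    patience: int = 8


@dataclass
class DetectorModel:
    """Trained classifier: architecture descriptor + learned parameters.

    ``metadata`` records the training seed, epochs actually run and a
    fingerprint of the training data so a checkpoint is self-describing.
    """

    hidden: int
    params: dict
    metadata: dict = field(default_factory=dict)

    def predict(self, windows_x: np.ndarray) -> np.ndarray:
        """Probabilities in [0, 1] for a batch of windows (B, T) in ms.

        Windows are scored one at a time: BLAS matrix products round
        differently for different batch shapes, and per-window evaluation
        guarantees that a window's probability never depends on what else is
        in the batch (stream/batch bit-equality).
        """
        X = np.asarray(windows_x, dtype=float) * INPUT_SCALE
        if X.ndim == 1:
            X = X[None, :]
        return np.concatenate(
            [nn.predict_proba(self.params, X[i : i + 1]) for i in range(len(X))]
        )

    def save(self, path) -> None:
        payload = {
            "format": CHECKPOINT_FORMAT,
            "hidden": self.hidden,
            "metadata": self.metadata,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "DetectorModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(
                f"{path}: not a detector checkpoint (format={payload.get('format')!r})"
            )
        params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return cls(hidden=payload["hidden"], params=params, metadata=payload["metadata"])


def make_windows(series: RRSeries, cfg: WindowingConfig) -> List[Window]:
    """Cut a series into sliding windows of beats.

    Window count is ``floor((N - window_len)/stride) + 1``.  A labelled
    window takes the majority per-beat label; ties go to AF (the
    conservative, sensitivity-preserving choice for a screening detector).
    """
    n = len(series)
    if n < cfg.window_len:
        raise ValueError(
            f"series has {n} beats; at least {cfg.window_len} needed for one window"
        )
    windows: List[Window] = []
    for start in range(0, n - cfg.window_len + 1, cfg.stride):
        stop = start + cfg.window_len
        label = None
        if series.labels is not None:
            af_count = int(np.sum(series.labels[start:stop] == AF))
            label = AF if af_count * 2 >= cfg.window_len else NSR
        windows.append(
            Window(
                intervals=series.intervals[start:stop],
                label=label,
                end_time=float(series.beat_times[stop - 1]),
            )
        )
    return windows


def _stack(windows: Sequence[Window]) -> np.ndarray:
    return np.stack([w.intervals for w in windows]).astype(float)


def _labels_to_y(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([1.0 if lab == AF else 0.0 for lab in labels])


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(
    windows: Sequence[Window],
    labels: Sequence[str],
    seed: int,
    config: Optional[TrainConfig] = None,
) -> DetectorModel:
    """Train the classifier on labelled windows.

    Deterministic for a given (data, seed, config): all randomness — weight
    init, validation split, batch shuffling — flows from one seeded
    generator.  Early stopping monitors binary cross-entropy on a held-back
    validation fraction and restores the best epoch's weights.
    """
    cfg = config or TrainConfig()
    y = _labels_to_y(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both NSR and AF windows")
    X = _stack(windows) * INPUT_SCALE

    rng = np.random.default_rng(seed)
    params = nn.init_params(cfg.hidden, rng)

    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    # keep both classes in the training split even for tiny inputs
    if len(np.unique(y[tr_idx])) < 2:
        tr_idx, val_idx = perm, perm[:n_val]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    opt = nn.Adam(params, lr=cfg.lr)
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = 0
    epochs_run = 0
    stall = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(ytr))
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            _, grads = nn.loss_and_grads(params, Xtr[idx], ytr[idx])
            opt.step(params, grads)
        pval = nn.predict_proba(params, Xval)
        pc = np.clip(pval, 1e-12, 1 - 1e-12)
        val_loss = float(-np.mean(yval * np.log(pc) + (1 - yval) * np.log(1 - pc)))
        epochs_run = epoch
        if val_loss < best_loss - 1e-5:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    metadata = {
        "seed": int(seed),
        "epochs_run": epochs_run,
        "best_epoch": best_epoch,
        "val_loss": best_loss,
        "n_windows": n,
        "window_len": int(X.shape[1]),
        "data_fingerprint": _fingerprint(X, y),
    }
    return DetectorModel(hidden=cfg.hidden, params=best_params, metadata=metadata)


def predict_trace(
    model: DetectorModel, series: RRSeries, cfg: WindowingConfig
) -> ProbabilityTrace:
    """Score every window of a series; one probability per window.

    Each probability is stamped at its window's final beat time, so feeding
    the series incrementally and re-predicting reproduces the probabilities
    of every window that was already complete.
    """
    windows = make_windows(series, cfg)
    probs = model.predict(_stack(windows))
    times = np.asarray([w.end_time for w in windows])
    return ProbabilityTrace(times=times, probabilities=probs)


def _classify(model: DetectorModel, X_ms: np.ndarray) -> np.ndarray:
    return (model.predict(X_ms) > 0.5).astype(float)


def _report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return EvalReport(tp, tn, fp, fn)


def crossvalidate_10fold(
    windows: Sequence[Window],
    labels: Sequence[str],
    seed: int,
    config: Optional[TrainConfig] = None,
) -> Tuple[EvalReport, List[EvalReport]]:
    """Stratified ten-fold cross-validation.

    Folds are disjoint, cover every window and differ in size by at most
    one.  Returns the pooled report (confusion counts summed over the ten
    test folds) and the per-fold reports.
    """
    y = _labels_to_y(labels)
    if min(np.sum(y == 1), np.sum(y == 0)) < 10:
        raise ValueError("ten-fold cross-validation needs at least 10 windows per class")
    X_ms = _stack(windows)
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed % (2**31))
    fold_reports: List[EvalReport] = []
    pooled = EvalReport(0, 0, 0, 0)
    for k, (tr, te) in enumerate(skf.split(X_ms, y)):
        model = train([windows[i] for i in tr], [labels[i] for i in tr],
                      seed=seed + 1000 * (k + 1), config=config)
        rep = _report_from_predictions(y[te], _classify(model, X_ms[te]))
        fold_reports.append(rep)
        pooled = pooled + rep
    return pooled, fold_reports


def evaluate_holdout(
    model: DetectorModel, windows: Sequence[Window], labels: Sequence[str]
) -> EvalReport:
    """Evaluate a trained model on labelled windows it never saw."""
    if len(windows) == 0:
        raise ValueError("hold-out evaluation set is empty")
    y = _labels_to_y(labels)
    return _report_from_predictions(y, _classify(model, _stack(windows)))


def make_benchmark(
    n_per_class: int = 200,
    beats: int = 120,
    seed: int = 7,
    params: Optional[RhythmParams] = None,
) -> List[RRSeries]:
    """The standard synthetic benchmark: single-rhythm short recordings.

    ``n_per_class`` NSR-only plus ``n_per_class`` AF-only recordings of
    exactly ``beats`` beats each, with independent per-recording seeds
    spawned from ``seed``.  Each recording is generated slightly longer than
    needed and truncated to the requested beat count.
    """
    base = params or RhythmParams()
    recordings: List[RRSeries] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
    for i in range(n_per_class):
        for j, rhythm in enumerate((NSR, AF)):
            p = base.with_seed(int(child_seeds[2 * i + j]) % (2**31))
            mean = p.nsr_mean_rr if rhythm == NSR else p.af_mean_rr
            duration = beats * mean / 1000.0 * 1.3
            rec = generate_segment(p, rhythm, duration)
            if len(rec) < beats:  # pragma: no cover - 1.3 margin is ample
                rec = generate_segment(p, rhythm, duration * 1.5)
            recordings.append(rec.slice_beats(0, beats))
    return recordings
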