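"""Bidirectional LSTM sequence classifier, implemented directly in NumPy.

The topology is the three-layer design used for AF probability estimation:

    input (one RR interval per time step)
      -> bidirectional LSTM (hidden width H per direction)
      -> global max pooling over time (per feature)
      -> fully connected layer -> sigmoid -> AF probability in [0, 1]

Training is full backpropagation through time with the Adam optimiser and a
binary cross-entropy loss.  Everything is plain NumPy so runs are exactly
reproducible from a seed on any machine; the analytic gradients are checked
against finite differences in the test suite.

Array conventions: a batch is ``X`` of shape ``(B, T)`` — B windows of T
scalar inputs (interval values); labels ``y`` of shape ``(B,)`` in {0, 1}.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

__all__ = ["init_params", "forward", "loss_and_grads", "predict_proba", "Adam"]

Params = Dict[str, np.ndarray]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable in both tails
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_params(hidden: int, rng: np.random.Generator) -> Params:
    """Initialise all weights uniformly in ±1/sqrt(hidden).

    The forget-gate bias is shifted by +1 so memory cells start out
    retentive, the usual trick for stable LSTM training.
    """
    k = 1.0 / np.sqrt(hidden)

    def u(*shape):
        return rng.uniform(-k, k, size=shape)

    params: Params = {}
    for d in ("f", "b"):  # forward / backward direction
        params[f"Wx_{d}"] = u(1, 4 * hidden)
        params[f"Wh_{d}"] = u(hidden, 4 * hidden)
        bias = u(4 * hidden)
        bias[hidden : 2 * hidden] += 1.0  # forget gate slice
        params[f"b_{d}"] = bias
    params["w_out"] = u(2 * hidden)
    params["b_out"] = u(1)
    return params


def _lstm_direction(
    X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray, reverse: bool
) -> Tuple[np.ndarray, dict]:
    """Run one LSTM direction over ``X`` (B, T); return hidden stack (B, T, H)."""
    B, T = X.shape
    H = Wh.shape[0]
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.zeros((B, T, H))
    cache = {"gates": {}, "h_prev": {}, "c_prev": {}, "tanh_c": {}, "order": list(order)}
    for t in cache["order"]:
        z = X[:, t : t + 1] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        cache["h_prev"][t] = h
        cache["c_prev"][t] = c
        c = f * c + i * g
        tanh_c = np.tanh(c)
        h = o * tanh_c
        cache["gates"][t] = (i, f, g, o)
        cache["tanh_c"][t] = tanh_c
        Hs[:, t, :] = h
    cache["Hs"] = Hs
    return Hs, cache


def _lstm_direction_backward(
    X: np.ndarray,
    Wh: np.ndarray,
    dHs: np.ndarray,
    cache: dict,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backprop through one direction; returns (dWx, dWh, db)."""
    B, T = X.shape
    H = Wh.shape[0]
    dWx = np.zeros((1, 4 * H))
    dWh = np.zeros((H, 4 * H))
    db = np.zeros(4 * H)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in reversed(cache["order"]):
        i, f, g, o = cache["gates"][t]
        tanh_c = cache["tanh_c"][t]
        dh = dHs[:, t, :] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c**2) + dc_next
        di = dc * g
        df = dc * cache["c_prev"][t]
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += X[:, t : t + 1].T @ dz
        dWh += cache["h_prev"][t].T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ Wh.T
    return dWx, dWh, db


def forward(params: Params, X: np.ndarray, *, want_cache: bool = False):
    """Forward pass; returns probabilities (B,) and optionally caches."""
    Hs_f, cache_f = _lstm_direction(X, params["Wx_f"], params["Wh_f"], params["b_f"], False)
    Hs_b, cache_b = _lstm_direction(X, params["Wx_b"], params["Wh_b"], params["b_b"], True)
    Hs = np.concatenate([Hs_f, Hs_b], axis=2)  # (B, T, 2H)
    argmax_t = np.argmax(Hs, axis=1)  # (B, 2H)
    pooled = np.take_along_axis(Hs, argmax_t[:, None, :], axis=1)[:, 0, :]
    logit = pooled @ params["w_out"] + params["b_out"][0]
    p = _sigmoid(logit)
    if not want_cache:
        return p
    return p, {
        "cache_f": cache_f,
        "cache_b": cache_b,
        "argmax_t": argmax_t,
        "pooled": pooled,
    }


def predict_proba(params: Params, X: np.ndarray) -> np.ndarray:
    return forward(params, X)


def loss_and_grads(params: Params, X: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and gradients for every parameter."""
    B, T = X.shape
    H = params["Wh_f"].shape[0]
    p, cache = forward(params, X, want_cache=True)
    eps = 1e-12
    pc = np.clip(p, eps, 1.0 - eps)
    loss = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))

    dlogit = (p - y) / B  # (B,)
    grads: Params = {}
    grads["w_out"] = cache["pooled"].T @ dlogit
    grads["b_out"] = np.array([dlogit.sum()])
    dpooled = np.outer(dlogit, params["w_out"])  # (B, 2H)

    # route pooled gradient back to the argmax time step of each feature
    dHs = np.zeros((B, T, 2 * H))
    b_idx = np.arange(B)[:, None]
    f_idx = np.arange(2 * H)[None, :]
    dHs[b_idx, cache["argmax_t"], f_idx] = dpooled

    dWx_f, dWh_f, db_f = _lstm_direction_backward(
        X, params["Wh_f"], dHs[:, :, :H], cache["cache_f"]
    )
    dWx_b, dWh_b, db_b = _lstm_direction_backward(
        X, params["Wh_b"], dHs[:, :, H:], cache["cache_b"]
    )
    grads.update(
        Wx_f=dWx_f, Wh_f=dWh_f, b_f=db_f, Wx_b=dWx_b, Wh_b=dWh_b, b_b=db_b
    )
    return loss, grads


class Adam:
    """Standard Adam optimiser over a parameter dict."""

    def __init__(self, params: Params, lr: float = 3e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
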