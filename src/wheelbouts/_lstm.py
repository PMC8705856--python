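"""Minimal numpy implementation of a stacked bidirectional LSTM sequence
labeler with per-timestep sigmoid output.

Network: input (B, T, D) -> [bidirectional LSTM] x n_layers -> dense (ReLU)
-> dense (sigmoid) -> probabilities (B, T).  Gate layout in the fused weight
matrices is [input, forget, cell, output].  Gradients are exact BPTT; the
test suite checks them against central finite differences.

Everything is deterministic given the ``numpy.random.Generator`` used for
initialization.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def init_params(
    rng: np.random.Generator,
    in_dim: int,
    hidden: int,
    n_layers: int,
    dense: int,
) -> dict:
    """Initialize all weights; forget-gate biases start at 1."""
    p: dict[str, np.ndarray] = {}
    d = in_dim
    for layer in range(n_layers):
        for dirn in ("f", "b"):
            key = f"l{layer}{dirn}"
            p[f"Wx_{key}"] = _glorot(rng, d, 4 * hidden)
            p[f"Wh_{key}"] = _glorot(rng, hidden, 4 * hidden)
            b = np.zeros(4 * hidden)
            b[hidden : 2 * hidden] = 1.0
            p[f"b_{key}"] = b
        d = 2 * hidden
    p["Wd"] = _glorot(rng, d, dense)
    p["bd"] = np.zeros(dense)
    p["Wo"] = _glorot(rng, dense, 1)
    p["bo"] = np.zeros(1)
    return p


def _lstm_forward(X: np.ndarray, Wx, Wh, b):
    """One-direction LSTM over (B, T, D); returns hidden states and cache."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        z = X[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev_entry = h
        h = o * tc
        Hs[:, t] = h
        cache.append((X[:, t], h_prev_entry, c_prev, i, f, g, o, tc))
    return Hs, cache


def _lstm_backward(dHs: np.ndarray, cache, Wx, Wh):
    B, T, H = dHs.shape
    D = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.empty((B, T, D))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, tc = cache[t]
        dh = dHs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        dWx += x.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
    return dX, dWx, dWh, db


def _bilstm_forward(X: np.ndarray, p: dict, key: str):
    Hf, cf = _lstm_forward(X, p[f"Wx_{key}f"], p[f"Wh_{key}f"], p[f"b_{key}f"])
    Hb, cb = _lstm_forward(X[:, ::-1], p[f"Wx_{key}b"], p[f"Wh_{key}b"], p[f"b_{key}b"])
    return np.concatenate([Hf, Hb[:, ::-1]], axis=2), (cf, cb)


def forward(X: np.ndarray, p: dict, n_layers: int):
    """Full network forward pass; returns probabilities (B, T) and cache."""
    acts = [X]
    caches = []
    A = X
    for layer in range(n_layers):
        A, cache = _bilstm_forward(A, p, f"l{layer}")
        acts.append(A)
        caches.append(cache)
    Zd = A @ p["Wd"] + p["bd"]
    Dh = np.maximum(Zd, 0.0)
    logit = (Dh @ p["Wo"] + p["bo"])[..., 0]
    P = _sigmoid(logit)
    return P, (acts, caches, Zd, Dh)


def backward(P: np.ndarray, Y: np.ndarray, cache, p: dict, n_layers: int) -> dict:
    """Gradients of mean binary cross-entropy w.r.t. every parameter."""
    acts, caches, Zd, Dh = cache
    B, T = P.shape
    grads: dict[str, np.ndarray] = {}
    dlogit = (P - Y) / (B * T)  # (B, T)
    grads["Wo"] = Dh.reshape(-1, Dh.shape[-1]).T @ dlogit.reshape(-1, 1)
    grads["bo"] = np.array([dlogit.sum()])
    dDh = dlogit[..., None] @ p["Wo"].T[None]
    dZd = dDh * (Zd > 0)
    A_top = acts[n_layers]
    grads["Wd"] = A_top.reshape(-1, A_top.shape[-1]).T @ dZd.reshape(-1, dZd.shape[-1])
    grads["bd"] = dZd.sum(axis=(0, 1))
    dA = dZd @ p["Wd"].T
    for layer in range(n_layers - 1, -1, -1):
        key = f"l{layer}"
        cf, cb = caches[layer]
        H = p[f"Wh_{key}f"].shape[0]
        dXf, dWxf, dWhf, dbf = _lstm_backward(
            dA[:, :, :H], cf, p[f"Wx_{key}f"], p[f"Wh_{key}f"]
        )
        dXb, dWxb, dWhb, dbb = _lstm_backward(
            dA[:, ::-1, H:], cb, p[f"Wx_{key}b"], p[f"Wh_{key}b"]
        )
        grads[f"Wx_{key}f"], grads[f"Wh_{key}f"], grads[f"b_{key}f"] = dWxf, dWhf, dbf
        grads[f"Wx_{key}b"], grads[f"Wh_{key}b"], grads[f"b_{key}b"] = dWxb, dWhb, dbb
        dA = dXf + dXb[:, ::-1]
    return grads


def bce_loss(P: np.ndarray, Y: np.ndarray, eps: float = 1e-12) -> float:
    P = np.clip(P, eps, 1.0 - eps)
    return float(-np.mean(Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P)))


class Adam:
    """Plain Adam over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
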