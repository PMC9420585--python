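"""Minimal recurrent-network building blocks in numpy + numba.

Implements exactly what the segmenter needs: an LSTM layer run in either
time direction with full backpropagation through time, a per-timestep
affine classifier, softmax cross-entropy, inverted dropout, and Adam.
Arrays are time-major, (T, B, features).  Gate order in the fused weight
matrices is input, forget, cell, output; the forget-gate bias is
initialized to 1 so memory is retained early in training.

The per-timestep recurrences are compiled with numba; the input and
weight-gradient projections stay as single large numpy matmuls.  All
gradients are validated against central finite differences in the test
suite; keep any change here covered by that check.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_lstm_params(
    in_size: int, hidden: int, rng: np.random.Generator, dtype=np.float32
) -> dict[str, np.ndarray]:
    """Uniform(-k, k) with k = 1/sqrt(hidden); forget bias set to 1."""
    k = 1.0 / np.sqrt(hidden)
    p = {
        "Wx": rng.uniform(-k, k, (in_size, 4 * hidden)),
        "Wh": rng.uniform(-k, k, (hidden, 4 * hidden)),
        "b": np.zeros(4 * hidden),
    }
    p["b"][hidden : 2 * hidden] = 1.0
    return {k_: v.astype(dtype) for k_, v in p.items()}


@njit(cache=True)
def _fwd_loop(zx, Wh, reverse):
    """Recurrent forward pass.  zx: (T, B, 4H) = x@Wx + b, Wh: (H, 4H)."""
    T, B, H4 = zx.shape
    H = H4 // 4
    h = np.zeros((T, B, H), dtype=zx.dtype)
    c = np.zeros((T, B, H), dtype=zx.dtype)
    cprev = np.zeros((T, B, H), dtype=zx.dtype)
    hprev = np.zeros((T, B, H), dtype=zx.dtype)
    gates = np.zeros((T, B, H4), dtype=zx.dtype)

    hp = np.zeros((B, H), dtype=zx.dtype)
    cp = np.zeros((B, H), dtype=zx.dtype)
    for step in range(T):
        t = T - 1 - step if reverse else step
        z = zx[t] + np.dot(hp, Wh)
        for b_ in range(B):
            for j in range(H):
                zi, zf = z[b_, j], z[b_, H + j]
                zg, zo = z[b_, 2 * H + j], z[b_, 3 * H + j]
                ig = 1.0 / (1.0 + np.exp(-zi))
                fg = 1.0 / (1.0 + np.exp(-zf))
                gg = np.tanh(zg)
                og = 1.0 / (1.0 + np.exp(-zo))
                cc = fg * cp[b_, j] + ig * gg
                gates[t, b_, j] = ig
                gates[t, b_, H + j] = fg
                gates[t, b_, 2 * H + j] = gg
                gates[t, b_, 3 * H + j] = og
                cprev[t, b_, j] = cp[b_, j]
                hprev[t, b_, j] = hp[b_, j]
                c[t, b_, j] = cc
                h[t, b_, j] = og * np.tanh(cc)
        hp = h[t].copy()
        cp = c[t].copy()
    return h, c, cprev, hprev, gates


@njit(cache=True)
def _bwd_loop(dh, gates, c, cprev, WhT, reverse):
    """Recurrent backward pass; returns the fused pre-activation grads dz."""
    T, B, H = dh.shape
    dz = np.zeros((T, B, 4 * H), dtype=dh.dtype)
    dh_next = np.zeros((B, H), dtype=dh.dtype)
    dc_next = np.zeros((B, H), dtype=dh.dtype)
    for step in range(T):
        # opposite direction of the forward walk
        t = step if reverse else T - 1 - step
        for b_ in range(B):
            for j in range(H):
                ig = gates[t, b_, j]
                fg = gates[t, b_, H + j]
                gg = gates[t, b_, 2 * H + j]
                og = gates[t, b_, 3 * H + j]
                tc = np.tanh(c[t, b_, j])
                dht = dh[t, b_, j] + dh_next[b_, j]
                do = dht * tc
                dc = dht * og * (1.0 - tc * tc) + dc_next[b_, j]
                dz[t, b_, j] = dc * gg * ig * (1.0 - ig)
                dz[t, b_, H + j] = dc * cprev[t, b_, j] * fg * (1.0 - fg)
                dz[t, b_, 2 * H + j] = dc * ig * (1.0 - gg * gg)
                dz[t, b_, 3 * H + j] = do * og * (1.0 - og)
                dc_next[b_, j] = dc * fg
        dh_next = np.dot(dz[t], WhT)
    return dz


def lstm_forward(
    x: np.ndarray, params: dict[str, np.ndarray], reverse: bool = False
) -> tuple[np.ndarray, dict]:
    """Run an LSTM over (T, B, I) input; return hidden states (T, B, H).

    `reverse` processes the sequence back-to-front (the output stays in
    natural time order), giving the backward half of a BiLSTM.
    """
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
    zx = np.ascontiguousarray(x @ Wx + b)
    h, c, cprev, hprev, gates = _fwd_loop(zx, np.ascontiguousarray(Wh), reverse)
    cache = {"x": x, "gates": gates, "c": c, "cprev": cprev, "hprev": hprev,
             "reverse": reverse}
    return h, cache


def lstm_backward(
    dh: np.ndarray, params: dict[str, np.ndarray], cache: dict
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """BPTT: gradient of a scalar loss w.r.t. inputs and parameters."""
    x, gates, c, cprev, hprev = (
        cache["x"], cache["gates"], cache["c"], cache["cprev"], cache["hprev"],
    )
    Wx, Wh = params["Wx"], params["Wh"]
    T, B, H = dh.shape
    dz = _bwd_loop(
        np.ascontiguousarray(dh), gates, c, cprev,
        np.ascontiguousarray(Wh.T), cache["reverse"],
    )
    I = x.shape[2]
    x2d = x.reshape(T * B, I)
    dz2d = dz.reshape(T * B, 4 * H)
    grads = {
        "Wx": x2d.T @ dz2d,
        "Wh": hprev.reshape(T * B, H).T @ dz2d,
        "b": dz2d.sum(axis=0),
    }
    dx = dz @ Wx.T
    return dx, grads


def softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-sample cross-entropy and its gradient w.r.t. logits.

    logits: (T, B, C); targets: (T, B) integer classes.
    """
    p = softmax(logits.astype(np.float64))
    T, B, C = p.shape
    idx = (np.arange(T)[:, None], np.arange(B)[None, :], targets)
    loss = float(-np.log(np.clip(p[idx], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[idx] -= 1.0
    dlogits /= T * B
    return loss, dlogits.astype(logits.dtype)


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= (
                self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)
            ).astype(params[k].dtype)
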