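"""Minimal batched LSTM with exact backpropagation through time, in NumPy.

Single-layer LSTM with a linear read-out head, sufficient for the
initial-condition estimators this package trains (tens of input channels,
hidden sizes of a few hundred, sequences of ~50-100 steps).  Gate layout in
the fused weight matrices is ``[input, forget, cell, output]``; the forget
gate bias is initialized to +1.  All randomness flows through an explicit
``numpy.random.Generator`` so training is reproducible bit-for-bit.
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


def init_params(n_in: int, hidden: int, n_out: int, rng: np.random.Generator) -> dict:
    """Glorot-uniform weights, +1 forget-gate bias, zero head bias."""
    def glorot(fan_in, fan_out, shape):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, shape)

    b = np.zeros(4 * hidden)
    b[hidden:2 * hidden] = 1.0
    return {
        "Wx": glorot(n_in, hidden, (n_in, 4 * hidden)),
        "Wh": glorot(hidden, hidden, (hidden, 4 * hidden)),
        "b": b,
        "Wo": glorot(hidden, n_out, (hidden, n_out)),
        "bo": np.zeros(n_out),
    }


def forward(params: dict, X: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run the LSTM over ``X`` of shape (B, T, n_in).

    Returns the head outputs (B, T, n_out) and a cache for ``backward``.
    """
    B, T, _ = X.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    gates = np.empty((B, T, 4 * H))
    cells = np.empty((B, T, H))
    hiddens = np.empty((B, T, H))
    tanh_c = np.empty((B, T, H))
    for t in range(T):
        z = X[:, t, :] @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[:, t, :] = np.concatenate([i, f, g, o], axis=1)
        cells[:, t, :] = c
        tanh_c[:, t, :] = tc
        hiddens[:, t, :] = h
    Y = hiddens @ params["Wo"] + params["bo"]
    cache = {"X": X, "gates": gates, "cells": cells, "tanh_c": tanh_c,
             "hiddens": hiddens}
    return Y, cache


def backward(params: dict, cache: dict, dY: np.ndarray) -> dict:
    """Exact gradients of a scalar loss with upstream gradient ``dY``."""
    X, gates = cache["X"], cache["gates"]
    cells, tanh_c, hiddens = cache["cells"], cache["tanh_c"], cache["hiddens"]
    B, T, _ = X.shape
    H = params["Wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["Wo"] = np.einsum("bth,btn->hn", hiddens, dY)
    grads["bo"] = dY.sum(axis=(0, 1))
    dh_out = dY @ params["Wo"].T

    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H:2 * H]
        g = gates[:, t, 2 * H:3 * H]
        o = gates[:, t, 3 * H:]
        tc = tanh_c[:, t, :]
        dh = dh_out[:, t, :] + dh_next
        dc = dc_next + dh * o * (1.0 - tc * tc)
        c_prev = cells[:, t - 1, :] if t > 0 else np.zeros((B, H))
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        do = dh * tc
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ], axis=1)
        grads["Wx"] += X[:, t, :].T @ dz
        grads["b"] += dz.sum(axis=0)
        if t > 0:
            grads["Wh"] += hiddens[:, t - 1, :].T @ dz
        dh_next = dz @ params["Wh"].T
        dc_next = dc * f
    return grads


def clip_grad_norm(grads: dict, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k in params:
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * grads[k] ** 2
            params[k] -= self.lr * (self.m[k] / bias1) / (
                np.sqrt(self.v[k] / bias2) + self.eps
            )
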