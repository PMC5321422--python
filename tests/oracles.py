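"""Independent brute-force oracles used to verify the vectorized implementations.

Everything here is deliberately written the slow, obvious way (explicit
nested loops, direct DFT sums, QR/SVD canonical correlations, exhaustive
nearest-neighbour search) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def sigmoid_ref(s):
    return 1.0 / (1.0 + np.exp(-np.asarray(s, dtype=np.float64)))


def c1_forward_loops(X: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Channel-combining layer, one scalar at a time.  X: (n_fs, n_ch)."""
    n_fs, n_ch = X.shape
    n_maps = w.shape[0]
    out = np.zeros((n_maps, n_fs))
    for k in range(n_maps):
        for p in range(n_fs):
            s = b[k]
            for j in range(n_ch):
                s += X[p, j] * w[k, j]
            out[k, p] = sigmoid_ref(s)
    return out


def c2_forward_loops(x1: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spectral convolution layer.  x1: (n_maps, n_fs); w: (out, in, kern)."""
    n_in, n_fs = x1.shape
    n_out, _, kern = w.shape
    units = n_fs - kern + 1
    out = np.zeros((n_out, units))
    for k in range(n_out):
        for p in range(units):
            s = b[k]
            for i in range(n_in):
                for j in range(kern):
                    s += x1[i, p + j] * w[k, i, j]
            out[k, p] = sigmoid_ref(s)
    return out


def dense_forward_loops(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fully connected layer on a flat vector."""
    out = np.zeros(w.shape[0])
    for p in range(w.shape[0]):
        s = b[p]
        for j in range(w.shape[1]):
            s += x[j] * w[p, j]
        out[p] = sigmoid_ref(s)
    return out


def dft_magnitudes(x: np.ndarray, n_fft: int, bins: np.ndarray) -> np.ndarray:
    """O(n^2) direct discrete-Fourier sum of a zero-padded signal."""
    n = x.shape[0]
    out = np.zeros((bins.size,) + x.shape[1:])
    for bi, k in enumerate(bins):
        acc = np.zeros(x.shape[1:], dtype=complex)
        for t in range(n):
            acc = acc + x[t] * np.exp(-2j * np.pi * k * t / n_fft)
        out[bi] = np.abs(acc)
    return out


def cca_svd(X: np.ndarray, Y: np.ndarray) -> float:
    """Max canonical correlation via QR-whitening + SVD (no ridge)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, _ = np.linalg.qr(Xc)
    qy, _ = np.linalg.qr(Yc)
    return float(np.linalg.svd(qx.T @ qy, compute_uv=False).max())


def knn_bruteforce(train_X, train_y, query, k: int):
    """Exhaustive Euclidean k-NN with majority vote.

    Vote ties resolve to the nearest neighbour's label, then to the
    smallest label — the same convention as the implementation, so any
    disagreement flags a search/vote bug, not a convention mismatch.
    """
    d = np.sqrt(((train_X - query) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    labels = np.asarray(train_y)[order]
    values, counts = np.unique(labels, return_counts=True)
    winners = values[counts == counts.max()]
    if winners.size == 1:
        return winners[0]
    return labels[0] if labels[0] in winners else winners.min()


def finite_difference_grads(loss_fn, weights: dict, eps: float = 1e-5) -> dict:
    """Central finite differences of a scalar loss over every parameter."""
    grads = {}
    for key, arr in weights.items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = loss_fn()
            arr[idx] = orig - eps
            lm = loss_fn()
            arr[idx] = orig
            g[idx] = (lp - lm) / (2.0 * eps)
        grads[key] = g
    return grads
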