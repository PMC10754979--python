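"""Fused numerical kernels for the training hot path.

Batch normalisation and the ADAM update are memory-bandwidth-bound in pure
NumPy (each costs several full-array passes through temporaries); the JIT
kernels here fuse them into one or two passes.  Everything degrades
gracefully to NumPy if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def _bn_stats(x):
    """Per-channel mean and variance of a [N, C, H, W] array."""
    n, c, h, w = x.shape
    m = n * h * w
    mu = np.zeros(c, dtype=np.float64)
    sq = np.zeros(c, dtype=np.float64)
    for i in range(n):
        for j in range(c):
            s = 0.0
            ss = 0.0
            for k in range(h):
                for l in range(w):
                    v = x[i, j, k, l]
                    s += v
                    ss += v * v
            mu[j] += s
            sq[j] += ss
    mu /= m
    var = sq / m - mu * mu
    for j in range(c):
        if var[j] < 0.0:
            var[j] = 0.0
    return mu, var


@njit(cache=True, fastmath=True)
def _bn_apply(x, mu, inv, gamma, beta, xhat, out):
    n, c, h, w = x.shape
    for i in range(n):
        for j in range(c):
            mj, ij, gj, bj = mu[j], inv[j], gamma[j], beta[j]
            for k in range(h):
                for l in range(w):
                    v = (x[i, j, k, l] - mj) * ij
                    xhat[i, j, k, l] = v
                    out[i, j, k, l] = gj * v + bj


@njit(cache=True, fastmath=True)
def _bn_backward_train(g, xhat, gamma, inv, gx, dgamma, dbeta):
    n, c, h, w = g.shape
    m = n * h * w
    s1 = np.zeros(c, dtype=np.float64)
    s2 = np.zeros(c, dtype=np.float64)
    for i in range(n):
        for j in range(c):
            a = 0.0
            bsum = 0.0
            for k in range(h):
                for l in range(w):
                    gv = g[i, j, k, l]
                    a += gv
                    bsum += gv * xhat[i, j, k, l]
            s1[j] += a
            s2[j] += bsum
    for j in range(c):
        dbeta[j] = s1[j]
        dgamma[j] = s2[j]
    for i in range(n):
        for j in range(c):
            gj, ij = gamma[j], inv[j]
            c1 = s1[j] / m
            c2 = s2[j] / m
            for k in range(h):
                for l in range(w):
                    gx[i, j, k, l] = ij * gj * (
                        g[i, j, k, l] - c1 - xhat[i, j, k, l] * c2)


@njit(cache=True, fastmath=True)
def _adam_update(p, g, m, v, lr, b1, b2, bc1, bc2, clip, eps):
    """Fused per-learnable clip + ADAM moment update + parameter step."""
    sq = 0.0
    for i in range(g.size):
        sq += g.flat[i] * g.flat[i]
    norm = np.sqrt(sq)
    scale = clip / norm if norm > clip else 1.0
    for i in range(p.size):
        gi = g.flat[i] * scale
        m.flat[i] += (1.0 - b1) * (gi - m.flat[i])
        v.flat[i] += (1.0 - b2) * (gi * gi - v.flat[i])
        mh = m.flat[i] / bc1
        vh = v.flat[i] / bc2
        p.flat[i] -= lr * mh / (np.sqrt(vh) + eps)
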