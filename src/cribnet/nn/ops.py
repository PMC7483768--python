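"""Low-level numeric kernels for the CNN engine.

The 3x3 convolutions dominate the runtime, so their forward pass and weight
gradient are numba-compiled loops laid out channels-first with contiguous
inner loops over the image width (these vectorize well on a single core).
The input gradient reuses the forward kernel on the padded output gradient
with a transposed, spatially flipped filter bank.  The cheaper 2x2-stride-2
and 1x1 convolutions go through numpy einsum.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def conv3x3_forward(xp, w, b, y):  # pragma: no cover - numba
    """y[n,o,i,j] = b[o] + sum_{c,di,dj} w[o,c,di,dj] * xp[n,c,i+di,j+dj].

    ``xp`` is the input already zero-padded by 1 on both spatial axes.  The
    inner loop fuses the three kernel columns into a single row pass.
    """
    n_b, c_in, hp, wp = xp.shape
    c_out = w.shape[0]
    h = hp - 2
    wd = wp - 2
    for n in range(n_b):
        for o in range(c_out):
            yv = y[n, o]
            for i in range(h):
                row = yv[i]
                for j in range(wd):
                    row[j] = b[o]
            for c in range(c_in):
                for di in range(3):
                    w0 = w[o, c, di, 0]
                    w1 = w[o, c, di, 1]
                    w2 = w[o, c, di, 2]
                    for i in range(h):
                        xrow = xp[n, c, i + di]
                        yrow = yv[i]
                        for j in range(wd):
                            yrow[j] += (w0 * xrow[j] + w1 * xrow[j + 1]
                                        + w2 * xrow[j + 2])


@njit(cache=True, fastmath=True)
def conv3x3_dw(xp, dy, dw):  # pragma: no cover - numba
    """dw[o,c,di,dj] = sum_{n,i,j} xp[n,c,i+di,j+dj] * dy[n,o,i,j]."""
    n_b, c_in, hp, wp = xp.shape
    c_out = dy.shape[1]
    h = hp - 2
    wd = wp - 2
    for o in range(c_out):
        for c in range(c_in):
            for di in range(3):
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                for n in range(n_b):
                    for i in range(h):
                        xrow = xp[n, c, i + di]
                        drow = dy[n, o, i]
                        for j in range(wd):
                            d = drow[j]
                            s0 += xrow[j] * d
                            s1 += xrow[j + 1] * d
                            s2 += xrow[j + 2] * d
                dw[o, c, di, 0] = s0
                dw[o, c, di, 1] = s1
                dw[o, c, di, 2] = s2


def conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution, channels-first."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.empty((x.shape[0], w.shape[0], x.shape[2], x.shape[3]), dtype=x.dtype)
    conv3x3_forward(xp, w, b, y)
    return y


def conv3x3_backward(xp: np.ndarray, w: np.ndarray, dy: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of a same-padded 3x3 convolution."""
    dw = np.empty_like(w)
    conv3x3_dw(xp, dy, dw)
    db = dy.sum(axis=(0, 2, 3))
    # full correlation: conv of padded dy with channel-transposed, flipped w
    w_rot = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dx = np.empty((dy.shape[0], w.shape[1], dy.shape[2], dy.shape[3]), dtype=dy.dtype)
    conv3x3_forward(dyp, w_rot, np.zeros(w.shape[1], dtype=dy.dtype), dx)
    return dx, dw, db


@njit(cache=True, fastmath=True)
def _conv2x2s2_fwd(x, w, b, y):  # pragma: no cover - numba
    n_b, c_in, h, wd = x.shape
    c_out = w.shape[0]
    ho = h // 2
    wo = wd // 2
    for n in range(n_b):
        for o in range(c_out):
            yv = y[n, o]
            for i in range(ho):
                row = yv[i]
                for j in range(wo):
                    row[j] = b[o]
            for c in range(c_in):
                for a in range(2):
                    w0 = w[o, c, a, 0]
                    w1 = w[o, c, a, 1]
                    for i in range(ho):
                        xrow = x[n, c, 2 * i + a]
                        yrow = yv[i]
                        for j in range(wo):
                            yrow[j] += w0 * xrow[2 * j] + w1 * xrow[2 * j + 1]


@njit(cache=True, fastmath=True)
def _conv2x2s2_bwd(x, w, dy, dx, dw):  # pragma: no cover - numba
    n_b, c_in, h, wd = x.shape
    c_out = w.shape[0]
    ho = h // 2
    wo = wd // 2
    for o in range(c_out):
        for c in range(c_in):
            for a in range(2):
                s0 = 0.0
                s1 = 0.0
                for n in range(n_b):
                    for i in range(ho):
                        xrow = x[n, c, 2 * i + a]
                        drow = dy[n, o, i]
                        for j in range(wo):
                            d = drow[j]
                            s0 += xrow[2 * j] * d
                            s1 += xrow[2 * j + 1] * d
                dw[o, c, a, 0] = s0
                dw[o, c, a, 1] = s1
    # stride 2, kernel 2: output windows do not overlap, so dx is a direct sum
    for n in range(n_b):
        for c in range(c_in):
            for a in range(2):
                for i in range(ho):
                    xrow = dx[n, c, 2 * i + a]
                    for o in range(c_out):
                        w0 = w[o, c, a, 0]
                        w1 = w[o, c, a, 1]
                        drow = dy[n, o, i]
                        for j in range(wo):
                            xrow[2 * j] += w0 * drow[j]
                            xrow[2 * j + 1] += w1 * drow[j]


def conv2x2s2(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 stride-2 convolution (learned downsampling)."""
    n, c, h, wd = x.shape
    y = np.empty((n, w.shape[0], h // 2, wd // 2), dtype=x.dtype)
    _conv2x2s2_fwd(x, w, b, y)
    return y


def conv2x2s2_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dx = np.zeros_like(x)
    dw = np.empty_like(w)
    _conv2x2s2_bwd(x, w, dy, dx, dw)
    db = dy.sum(axis=(0, 2, 3))
    return dx, dw, db


@njit(cache=True, fastmath=True)
def bn_forward_train(x, gamma, beta, eps, out, xhat, mean, var):
    # pragma: no cover - numba
    """Per-channel batch norm (training): fills out, xhat, mean, var."""
    n_b, c_n, h, w = x.shape
    n = n_b * h * w
    for c in range(c_n):
        acc = 0.0
        acc2 = 0.0
        for nb in range(n_b):
            plane = x[nb, c]
            for i in range(h):
                row = plane[i]
                for j in range(w):
                    v = row[j]
                    acc += v
                    acc2 += v * v
        m = acc / n
        va = acc2 / n - m * m
        if va < 0.0:
            va = 0.0
        mean[c] = m
        var[c] = va
        istd = 1.0 / np.sqrt(va + eps)
        g = gamma[c]
        b_ = beta[c]
        for nb in range(n_b):
            planei = x[nb, c]
            planeh = xhat[nb, c]
            planeo = out[nb, c]
            for i in range(h):
                rowi = planei[i]
                rowh = planeh[i]
                rowo = planeo[i]
                for j in range(w):
                    xh = (rowi[j] - m) * istd
                    rowh[j] = xh
                    rowo[j] = g * xh + b_


@njit(cache=True, fastmath=True)
def bn_backward(xhat, gamma, invstd, dy, dx, dgamma, dbeta):
    # pragma: no cover - numba
    n_b, c_n, h, w = xhat.shape
    n = n_b * h * w
    for c in range(c_n):
        s1 = 0.0
        s2 = 0.0
        for nb in range(n_b):
            ph = xhat[nb, c]
            pd = dy[nb, c]
            for i in range(h):
                rh = ph[i]
                rd = pd[i]
                for j in range(w):
                    d = rd[j]
                    s1 += d
                    s2 += d * rh[j]
        dgamma[c] = s2
        dbeta[c] = s1
        coef = gamma[c] * invstd[c]
        m1 = s1 / n
        m2 = s2 / n
        for nb in range(n_b):
            ph = xhat[nb, c]
            pd = dy[nb, c]
            px = dx[nb, c]
            for i in range(h):
                rh = ph[i]
                rd = pd[i]
                rx = px[i]
                for j in range(w):
                    rx[j] = coef * (rd[j] - m1 - rh[j] * m2)


def conv1x1(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    y = np.einsum("oc,nchw->nohw", w, x, optimize=True)
    return (y + b[None, :, None, None]).astype(x.dtype)


def conv1x1_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dw = np.einsum("nohw,nchw->oc", dy, x, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.einsum("oc,nohw->nchw", w, dy, optimize=True)
    return dx.astype(x.dtype), dw.astype(w.dtype), db


def channel_softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of an (N, L, h, w) tensor."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def channel_softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """dL/dlogits given dL/dprobs for a channel softmax."""
    dot = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - dot)
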