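"""Numba kernels for the CNN: direct 5x5 convolution and 3x3/2 max-pool.

Direct convolution beats im2col+GEMM on a single CPU core here because the
5x5 taps stay in registers and every input row is streamed once; the im2col
route multiplies memory traffic by the kernel area.  All kernels take
(B, C, H, W) float32 arrays; spatial padding (2 px) is done by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

K = 5  # kernel size; PAD = 2 handled by callers


@njit(fastmath=True, cache=True)
def conv5_forward(xp, w, bias, out):
    """out[b,co] = bias[co] + sum_ci w[co,ci] * xp[b,ci] (valid, xp padded)."""
    nb, cin, hp, wp = xp.shape
    cout = w.shape[0]
    h, wd = hp - (K - 1), wp - (K - 1)
    for bi in range(nb):
        for co in range(cout):
            acc = out[bi, co]
            for i in range(h):
                row = acc[i]
                for j in range(wd):
                    row[j] = bias[co]
            for ci in range(cin):
                for u in range(K):
                    w0 = w[co, ci, u, 0]
                    w1 = w[co, ci, u, 1]
                    w2 = w[co, ci, u, 2]
                    w3 = w[co, ci, u, 3]
                    w4 = w[co, ci, u, 4]
                    for i in range(h):
                        xrow = xp[bi, ci, i + u]
                        row = acc[i]
                        for j in range(wd):
                            row[j] += (w0 * xrow[j] + w1 * xrow[j + 1]
                                       + w2 * xrow[j + 2] + w3 * xrow[j + 3]
                                       + w4 * xrow[j + 4])


@njit(fastmath=True, cache=True)
def conv5_dw(xp, dout, dw):
    """dw[co,ci,u,v] += sum_{b,i,j} dout[b,co,i,j] * xp[b,ci,i+u,j+v].

    The loop nest keeps one (b, ci) input plane and one (b, co) gradient
    plane hot in cache while sweeping the 25 taps.
    """
    nb, cin, hp, wp = xp.shape
    cout = dout.shape[1]
    h, wd = hp - (K - 1), wp - (K - 1)
    for bi in range(nb):
        for ci in range(cin):
            for co in range(cout):
                for u in range(K):
                    s0 = np.float32(0.0)
                    s1 = np.float32(0.0)
                    s2 = np.float32(0.0)
                    s3 = np.float32(0.0)
                    s4 = np.float32(0.0)
                    for i in range(h):
                        drow = dout[bi, co, i]
                        xrow = xp[bi, ci, i + u]
                        for j in range(wd):
                            d = drow[j]
                            s0 += d * xrow[j]
                            s1 += d * xrow[j + 1]
                            s2 += d * xrow[j + 2]
                            s3 += d * xrow[j + 3]
                            s4 += d * xrow[j + 4]
                    dw[co, ci, u, 0] += s0
                    dw[co, ci, u, 1] += s1
                    dw[co, ci, u, 2] += s2
                    dw[co, ci, u, 3] += s3
                    dw[co, ci, u, 4] += s4


@njit(fastmath=True, cache=True)
def maxpool3s2_forward(x, out, arg):
    """Valid 3x3 stride-2 max-pool; ``arg`` stores the in-window argmax 0..8."""
    nb, c, h, w = x.shape
    ho, wo = out.shape[2], out.shape[3]
    for bi in range(nb):
        for ci in range(c):
            plane = x[bi, ci]
            for oi in range(ho):
                i0 = 2 * oi
                for oj in range(wo):
                    j0 = 2 * oj
                    best = plane[i0, j0]
                    bk = 0
                    for u in range(3):
                        row = plane[i0 + u]
                        for v in range(3):
                            val = row[j0 + v]
                            if val > best:
                                best = val
                                bk = 3 * u + v
                    out[bi, ci, oi, oj] = best
                    arg[bi, ci, oi, oj] = bk


@njit(fastmath=True, cache=True)
def maxpool3s2_backward(dout, arg, dx):
    """Scatter pooled gradients back to argmax positions (dx pre-zeroed)."""
    nb, c, ho, wo = dout.shape
    for bi in range(nb):
        for ci in range(c):
            for oi in range(ho):
                for oj in range(wo):
                    k = arg[bi, ci, oi, oj]
                    dx[bi, ci, 2 * oi + k // 3, 2 * oj + k % 3] += dout[bi, ci, oi, oj]
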