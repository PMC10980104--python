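"""JIT max-pool kernels.

The overlapping 4x4/stride-2 pool dominates the classifier's cost if written
with NumPy whole-array passes, so the forward/backward kernels are compiled
with numba. The max is separable: a running max along W, then along H, with
per-axis winning offsets stored for the backward scatter (ties -> lowest
offset). Rows/columns outside the input (the implicit -inf padding) are
skipped by bounds checks.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def pool_fwd(x, k, stride, pad):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    tmp = np.empty((n, c, h, wo), x.dtype)
    arg_w = np.empty((n, c, h, wo), np.int8)
    for nn in range(n):
        for cc in range(c):
            for ii in range(h):
                for j in range(wo):
                    j0 = j * stride - pad
                    best = -np.inf
                    bj = np.int8(0)
                    for dj in range(k):
                        jj = j0 + dj
                        if 0 <= jj < w:
                            v = x[nn, cc, ii, jj]
                            if v > best:
                                best = v
                                bj = np.int8(dj)
                    tmp[nn, cc, ii, j] = best
                    arg_w[nn, cc, ii, j] = bj
    out = np.empty((n, c, ho, wo), x.dtype)
    arg_h = np.empty((n, c, ho, wo), np.int8)
    for nn in range(n):
        for cc in range(c):
            for i in range(ho):
                i0 = i * stride - pad
                for j in range(wo):
                    best = -np.inf
                    bi = np.int8(0)
                    for di in range(k):
                        ii = i0 + di
                        if 0 <= ii < h:
                            v = tmp[nn, cc, ii, j]
                            if v > best:
                                best = v
                                bi = np.int8(di)
                    out[nn, cc, i, j] = best
                    arg_h[nn, cc, i, j] = bi
    return out, arg_h, arg_w


@njit(cache=False, fastmath=True)
def pool_bwd(dout, arg_h, arg_w, h, w, k, stride, pad):
    n, c, ho, wo = dout.shape
    dx = np.zeros((n, c, h, w), dout.dtype)
    for nn in range(n):
        for cc in range(c):
            for i in range(ho):
                i0 = i * stride - pad
                for j in range(wo):
                    ii = i0 + arg_h[nn, cc, i, j]
                    jj = j * stride - pad + arg_w[nn, cc, ii, j]
                    dx[nn, cc, ii, jj] += dout[nn, cc, i, j]
    return dx
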