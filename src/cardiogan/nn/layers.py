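"""Minimal feed-forward layer stack with manual backpropagation.

All layers operate on float32 NCHW arrays. Convolutions are evaluated as a
single GEMM over an im2col buffer, which is the fastest formulation available
to pure NumPy on one CPU core at the image sizes used here (<= 300 px).

Every layer exposes

* ``forward(x, train=True)`` -> output,
* ``backward(dout)`` -> gradient w.r.t. the input, with parameter gradients
  accumulated into ``.grads``,
* ``params`` / ``grads``: dicts keyed by parameter name.

Randomness is injected only through the ``rng`` passed to the initializers, so
a network built from a seeded generator is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

F32 = np.float32


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int,
           pad_value: float = 0.0) -> np.ndarray:
    """Unfold (N,C,H,W) into rows of receptive fields, shape (N*Ho*Wo, C*k*k)."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                   constant_values=pad_value)
    sn, sc, sh, sw = x.strides
    view = as_strided(x, (n, ho, wo, c, k, k),
                      (sn, sh * stride, sw * stride, sc, sh, sw))
    return view.reshape(n * ho * wo, c * k * k)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int,
           pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add rows back onto an (N,C,H,W) grid."""
    n, c, h, w = x_shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols6 = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + stride * ho:stride,
                j:j + stride * wo:stride] += cols6[:, :, i, j]
    if pad:
        out = out[:, :, pad:hp - pad, pad:wp - pad]
    return out


class Layer:
    """Base class; stateless layers keep empty ``params``/``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_std: float | None = None):
        super().__init__()
        std = w_std if w_std is not None else np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, std, (n_in, n_out)).astype(F32),
            "b": np.zeros(n_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, w_std: float | None = None):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = \
            c_in, c_out, k, stride, pad
        std = w_std if w_std is not None else np.sqrt(2.0 / (c_in * k * k))
        self.params = {
            "W": rng.normal(0.0, std, (c_out, c_in * k * k)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != self.c_in:
            raise ValueError(
                f"expected (N,{self.c_in},H,W) input, got {x.shape}")
        self._x_shape = x.shape
        n, _, h, w = x.shape
        ho, wo = _out_size(h, self.k, self.stride, self.pad), \
            _out_size(w, self.k, self.stride, self.pad)
        self._cols = im2col(x, self.k, self.stride, self.pad)
        out = self._cols @ self.params["W"].T + self.params["b"]
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, ho, wo = dout.shape
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.grads["W"] += d2.T @ self._cols
        self.grads["b"] += d2.sum(axis=0)
        dcols = d2 @ self.params["W"]
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution (the adjoint of Conv2d)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, w_std: float = 0.02):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = \
            c_in, c_out, k, stride, pad
        self.params = {
            "W": rng.normal(0.0, w_std, (c_in, c_out * k * k)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        s, k, p = self.stride, self.k, self.pad
        return (h - 1) * s - 2 * p + k, (w - 1) * s - 2 * p + k

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[1] != self.c_in:
            raise ValueError(
                f"expected (N,{self.c_in},H,W) input, got {x.shape}")
        n, _, h, w = x.shape
        ho, wo = self.out_hw(h, w)
        self._x2 = x.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_in)
        self._in_hw = (h, w)
        cols = self._x2 @ self.params["W"]
        out = col2im(cols, (n, self.c_out, ho, wo), self.k, self.stride,
                     self.pad)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        n = dout.shape[0]
        h, w = self._in_hw
        cols_d = im2col(dout, self.k, self.stride, self.pad)
        self.grads["W"] += self._x2.T @ cols_d
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        dx2 = cols_d @ self.params["W"].T
        return dx2.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    def __init__(self, c: int, rng: np.random.Generator | None = None,
                 momentum: float = 0.1, eps: float = 1e-5,
                 gamma_std: float = 0.0):
        super().__init__()
        gamma = np.ones(c, dtype=F32)
        if gamma_std and rng is not None:
            gamma = rng.normal(1.0, gamma_std, c).astype(F32)
        self.params = {"gamma": gamma, "beta": np.zeros(c, dtype=F32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def forward(self, x, train=True):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) \
            * self._inv[None, :, None, None]
        return self.params["gamma"][None, :, None, None] * self._xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, dout):
        n, c, h, w = dout.shape
        m = n * h * w
        axes = (0, 2, 3)
        self.grads["gamma"] += (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        term = dxhat.sum(axis=axes)[None, :, None, None]
        term2 = (dxhat * self._xhat).sum(axis=axes)[None, :, None, None]
        return (self._inv[None, :, None, None] / m) \
            * (m * dxhat - term - self._xhat * term2)


class MaxPool2d(Layer):
    """Max pooling; the window may overlap (e.g. window 4, stride 2, pad 1).

    Forward/backward run through compiled separable kernels (see ``_pool``);
    winning offsets are cached for the backward scatter.
    """

    def __init__(self, k: int, stride: int, pad: int):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=True):
        from ._pool import pool_fwd
        self._x_shape = x.shape
        x = np.ascontiguousarray(x)
        out, self._arg_h, self._arg_w = pool_fwd(x, self.k, self.stride,
                                                 self.pad)
        return out

    def backward(self, dout):
        from ._pool import pool_bwd
        _, _, h, w = self._x_shape
        dout = np.ascontiguousarray(dout)
        return pool_bwd(dout, self._arg_h, self._arg_w, h, w, self.k,
                        self.stride, self.pad)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=True):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in)
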