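"""Minimal 3-D convolutional layers with analytic gradients.

Arrays are laid out (batch, channels, depth, height, width).  Each layer
caches what its backward pass needs during forward; backward consumes the
upstream gradient and returns the gradient with respect to the input while
accumulating parameter gradients in place.  Gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """Same-padding stride-1 convolution, kernel k (odd).

    Computed as k^3 shifted-slice matrix products rather than one big
    im2col patch matrix — the patch matrix is k^3 times the input size and
    its construction dominates runtime on a CPU.
    """

    def __init__(self, cin: int, cout: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        fan_in = cin * kernel ** 3
        bound = np.sqrt(6.0 / fan_in)  # He-uniform
        self.kernel = kernel
        self.w = Param(rng.uniform(-bound, bound,
                                   (cout, cin, kernel, kernel, kernel)
                                   ).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        n, cin, d, h, w = x.shape
        cout = self.w.value.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp = xp
        self._spatial = (d, h, w)
        npts = d * h * w
        out = np.zeros((n, cout, npts), dtype=x.dtype)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, :, a:a + d, b:b + h, c:c + w]
                    ).reshape(n, cin, npts)
                    out += self.w.value[:, :, a, b, c] @ xs
        out = out.reshape(n, cout, d, h, w)
        return out + self.b.value[None, :, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        cout, cin = self.w.value.shape[:2]
        n = dout.shape[0]
        d, h, w = self._spatial
        npts = d * h * w
        doutmat = np.ascontiguousarray(dout).reshape(n, cout, npts)
        xp = self._xp
        dxp = np.zeros_like(xp)
        wt = self.w.value.transpose(1, 0, 2, 3, 4)  # (cin, cout, k, k, k)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, :, a:a + d, b:b + h, c:c + w]
                    ).reshape(n, cin, npts)
                    # (N, cout, P) @ (N, P, cin) summed over batch
                    self.w.grad[:, :, a, b, c] += np.matmul(
                        doutmat, xs.transpose(0, 2, 1)).sum(axis=0)
                    contrib = wt[:, :, a, b, c] @ doutmat  # (N, cin, P)
                    dxp[:, :, a:a + d, b:b + h, c:c + w] += contrib.reshape(
                        n, cin, d, h, w)
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return (self.gamma.value[None, :, None, None, None] * self._xhat
                + self.beta.value[None, :, None, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (2, 3, 4)
        xhat = self._xhat
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.gamma.value[None, :, None, None, None]
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        dx = self._inv_std * (dxhat - m1 - xhat * m2)
        self._xhat = None
        self._inv_std = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool3d(Layer):
    """Non-overlapping pooling with cubic window ``size``."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        n, c, d, h, w = x.shape
        if d % s or h % s or w % s:
            raise ValueError("spatial dimensions must divide the pool size")
        xr = x.reshape(n, c, d // s, s, h // s, s, w // s, s)
        out = xr.max(axis=(3, 5, 7))
        # mask distributing gradient evenly across ties
        expanded = out[:, :, :, None, :, None, :, None]
        mask = (xr == expanded)
        self._mask = mask / mask.sum(axis=(3, 5, 7), keepdims=True)
        self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dr = dout[:, :, :, None, :, None, :, None] * self._mask
        dx = dr.reshape(self._in_shape)
        self._mask = None
        return dx


class ConvTranspose3d(Layer):
    """Transposed convolution, kernel == stride (non-overlapping blocks).

    Doubles each spatial dimension when kernel = stride = 2.
    """

    def __init__(self, cin: int, cout: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = cin
        bound = np.sqrt(6.0 / fan_in)
        self.kernel = kernel
        self.w = Param(rng.uniform(-bound, bound,
                                   (cin, cout, kernel, kernel, kernel)
                                   ).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        k = self.kernel
        n, c, d, h, w = x.shape
        cout = self.w.value.shape[1]
        out = np.einsum("ncijk,cfabg->nfiajbkg", x, self.w.value,
                        optimize=True)
        out = out.reshape(n, cout, d * k, h * k, w * k)
        return out + self.b.value[None, :, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        n, cout, dk, hk, wk = dout.shape
        dr = dout.reshape(n, cout, dk // k, k, hk // k, k, wk // k, k)
        dr = dr.transpose(0, 1, 2, 4, 6, 3, 5, 7)  # n f i j k a b g
        self.w.grad += np.einsum("ncijk,nfijkabg->cfabg", self._x, dr,
                                 optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("nfijkabg,cfabg->ncijk", dr, self.w.value,
                       optimize=True)
        self._x = None
        return dx


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of an (N, C, ...) array."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
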