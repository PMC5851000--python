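"""Minimal layer zoo for the plot-VI regression network.

Implements exactly the pieces the architecture needs — same-padded 5x5
convolution, non-overlapping 2x2 max pooling, dense layers, ReLU and
inverted dropout — with explicit forward/backward passes on channels-last
float32 arrays of shape (N, H, W, C).  Convolutions are evaluated as matrix
products over im2col patches, which keeps a full training run tractable on a
single CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Patch matrix (N*H*W, k*k*C) for a same-padded stride-1 convolution.

    Columns are ordered (kh, kw, c).  Filled one kernel *row* at a time:
    within a padded image row the k*C values of a patch row are contiguous,
    so each copy moves long runs instead of gathering a 6-D strided view.
    """
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    xr = xp.reshape(n, h + 2 * p, (w + 2 * p) * c)
    cols = np.empty((n, h, w, k, k * c), dtype=x.dtype)
    for kh in range(k):
        win = sliding_window_view(xr[:, kh:kh + h, :], k * c, axis=2)[:, :, ::c, :]
        cols[:, :, :, kh, :] = win
    return cols.reshape(n * h * w, k * k * c)


class Conv2DSame(Layer):
    """Stride-1 convolution with odd kernel and zero same-padding.

    Evaluated as one GEMM over im2col patches.  Set ``skip_input_grad`` on
    the network's first layer: its input gradient is never consumed and is
    the single most expensive tensor of the backward pass.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, skip_input_grad: bool = False,
                 init_scale: float = 1.0):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding")
        self.in_c, self.out_c, self.k = in_channels, out_channels, kernel
        self.skip_input_grad = skip_input_grad
        fan_in = in_channels * kernel * kernel
        # He init times init_scale; weight rows ordered (kh, kw, c) to match
        # _im2col columns
        w = rng.normal(0.0, init_scale * np.sqrt(2.0 / fan_in),
                       size=(fan_in, out_channels))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(out_channels, dtype=np.float32))
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if c != self.in_c:
            raise ValueError(f"expected {self.in_c} input channels, got {c}")
        cols = _im2col(x, self.k)
        out = cols @ self.W.data + self.b.data
        if train:
            self._cols, self._in_shape = cols, x.shape
        return out.reshape(n, h, w, self.out_c)

    def backward(self, grad):
        n, h, w, _ = grad.shape
        g_flat = np.ascontiguousarray(grad).reshape(n * h * w, self.out_c)
        self.W.grad = (g_flat.T @ self._cols).T  # faster GEMM orientation
        self.b.grad = g_flat.sum(axis=0)
        self._cols = None
        if self.skip_input_grad:
            return None
        # gradient w.r.t. input = convolution of grad with the flipped,
        # channel-transposed kernel (same padding, stride 1)
        w4 = self.W.data.reshape(self.k, self.k, self.in_c, self.out_c)
        w_back = np.ascontiguousarray(
            w4[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(
                self.k * self.k * self.out_c, self.in_c)
        cols_g = _im2col(grad, self.k)
        return (cols_g @ w_back).reshape(self._in_shape)


class MaxPool2(Layer):
    """Non-overlapping 2x2 max pooling; trailing odd rows/columns dropped.

    Backward routes the gradient to the maximal element of each window; on
    exact ties it is split equally among the tied elements (a valid
    subgradient, and deterministic).
    """

    def __init__(self, size: int = 2):
        self.size = size
        self._cache = None

    def _windows(self, x):
        s = self.size
        n, h, w, c = x.shape
        h2, w2 = h // s, w // s
        return x[:, :h2 * s, :w2 * s, :].reshape(n, h2, s, w2, s, c)

    def forward(self, x, train=False, rng=None):
        xr = self._windows(x)
        out = xr.max(axis=(2, 4))
        if train:
            self._cache = (x, out)
        return out

    def backward(self, grad):
        x, out = self._cache
        xr = self._windows(x)
        mask = (xr == out[:, :, None, :, None, :]).astype(grad.dtype)
        counts = mask.sum(axis=(2, 4))
        scaled = (grad / counts)[:, :, None, :, None, :]
        s = self.size
        n, h, w, c = x.shape
        h2, w2 = h // s, w // s
        g = np.zeros_like(x)
        g[:, :h2 * s, :w2 * s, :] = (mask * scaled).reshape(n, h2 * s, w2 * s, c)
        self._cache = None
        return g


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with Glorot-uniform initialization."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init_scale: float = 1.0):
        a = init_scale * np.sqrt(6.0 / (in_features + out_features))
        self.W = Param(rng.uniform(-a, a, size=(in_features, out_features)).astype(np.float32))
        self.b = Param(np.zeros(out_features, dtype=np.float32))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, grad):
        self.W.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        g_in = grad @ self.W.data.T
        self._x = None
        return g_in


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at test time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g
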