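"""Minimal numpy neural-network layers used by the conditional VAE.

Only the operations the model needs are provided: 3x3/stride-2 convolutions
and their transposed counterparts (implemented as each other's adjoint),
batch normalization, ReLU, dense layers, and an Adam optimizer with a
warmup-then-cosine learning-rate schedule.  Everything is deterministic
given the RNG handed to the initializers; forward passes cache what the
matching backward pass needs.

Array convention: feature maps are channels-first ``(B, C, W, H)``.
"""

from __future__ import annotations

import math

import numpy as np

# kernel offsets of a 3x3 window, row-major
_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]

try:  # tight gather/scatter loops; numpy strided copies are the fallback
    import numba

    @numba.njit(cache=False)
    def _im2col_s2_kernel(xp, cols, wout, hout):  # pragma: no cover - jitted
        b_n, c_n = xp.shape[0], xp.shape[1]
        for b in range(b_n):
            for c in range(c_n):
                for di in range(3):
                    for dj in range(3):
                        t = di * 3 + dj
                        for i in range(wout):
                            row = di + 2 * i
                            for j in range(hout):
                                cols[b, c, t, i, j] = xp[b, c, row, dj + 2 * j]

    @numba.njit(cache=False)
    def _col2im_s2_kernel(cols, xp, wout, hout):  # pragma: no cover - jitted
        b_n, c_n = cols.shape[0], cols.shape[1]
        for b in range(b_n):
            for c in range(c_n):
                for di in range(3):
                    for dj in range(3):
                        t = di * 3 + dj
                        for i in range(wout):
                            row = di + 2 * i
                            for j in range(hout):
                                xp[b, c, row, dj + 2 * j] += cols[b, c, t, i, j]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _im2col_s2(xp: np.ndarray, wout: int, hout: int) -> np.ndarray:
    """Gather 3x3 stride-2 patches from a padded map ``(B, C, W+2, H+2)``.

    Returns ``(B, C, 9, wout, hout)``.
    """
    b, c = xp.shape[:2]
    cols = np.empty((b, c, 9, wout, hout), dtype=xp.dtype)
    if _HAVE_NUMBA:
        _im2col_s2_kernel(np.ascontiguousarray(xp), cols, wout, hout)
        return cols
    for t, (di, dj) in enumerate(_OFFSETS):
        cols[:, :, t] = xp[:, :, di:di + 2 * wout - 1:2, dj:dj + 2 * hout - 1:2]
    return cols


def _col2im_s2(cols: np.ndarray, wpad: int, hpad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col_s2`: scatter-add patches back to a padded map."""
    b, c, _, wout, hout = cols.shape
    xp = np.zeros((b, c, wpad, hpad), dtype=cols.dtype)
    if _HAVE_NUMBA:
        _col2im_s2_kernel(np.ascontiguousarray(cols), xp, wout, hout)
        return xp
    for t, (di, dj) in enumerate(_OFFSETS):
        xp[:, :, di:di + 2 * wout - 1:2, dj:dj + 2 * hout - 1:2] += cols[:, :, t]
    return xp


class Layer:
    """Base class: trainable arrays in ``params``, matching ``grads``."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _ConvCore:
    """Shared machinery of the 3x3, stride-2, pad-1 convolution.

    ``conv(x, w)`` maps ``(B, Cin, 2w, 2h) -> (B, Cout, w, h)``; its data
    adjoint maps the other way and is exactly the transposed convolution
    with output padding 1.
    """

    @staticmethod
    def conv(x: np.ndarray, w: np.ndarray):
        b, cin, win, hin = x.shape
        wout, hout = win // 2, hin // 2
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = _im2col_s2(xp, wout, hout).reshape(b, cin * 9, wout * hout)
        y = np.matmul(w, cols)  # (B, Cout, wout*hout)
        cout = w.shape[0]
        return y.reshape(b, cout, wout, hout), cols

    @staticmethod
    def conv_backward_data(dy: np.ndarray, w: np.ndarray, win: int, hin: int):
        b, cout, wout, hout = dy.shape
        cin = w.shape[1] // 9
        dcols = np.matmul(w.T, dy.reshape(b, cout, wout * hout))
        dcols = dcols.reshape(b, cin, 9, wout, hout)
        dxp = _col2im_s2(dcols, win + 2, hin + 2)
        return dxp[:, :, 1:-1, 1:-1]

    @staticmethod
    def conv_backward_weight(dy: np.ndarray, cols: np.ndarray):
        b, cout, wout, hout = dy.shape
        dyf = dy.reshape(b, cout, wout * hout)
        # sum over batch of dyf @ cols^T
        return np.einsum("bol,bkl->ok", dyf, cols)


class Conv2d(Layer):
    """3x3 convolution, stride 2, padding 1 (halves each spatial dim)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        fan_in = cin * 9
        w = rng.standard_normal((cout, fan_in)) * math.sqrt(2.0 / fan_in)
        self.w = w.astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, x, train=True):
        y, cols = _ConvCore.conv(x, self.w)
        self._cache = (cols, x.shape)
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        cols, (b, cin, win, hin) = self._cache
        self.grads[0][...] = _ConvCore.conv_backward_weight(dy, cols)
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        return _ConvCore.conv_backward_data(dy, self.w, win, hin)


class ConvTranspose2d(Layer):
    """3x3 transposed convolution, stride 2 (doubles each spatial dim).

    Implemented as the adjoint of :class:`Conv2d`: the forward pass is the
    convolution's backward-data pass and vice versa.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        # stored as the weight of the adjoint convolution: (cin, cout*9)
        fan_in = cin * 9
        w = rng.standard_normal((cin, cout * 9)) * math.sqrt(2.0 / fan_in)
        self.w = w.astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, x, train=True):
        b, cin, win, hin = x.shape
        y = _ConvCore.conv_backward_data(x, self.w, 2 * win, 2 * hin)
        self._cache = x
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        x = self._cache
        dx, cols = _ConvCore.conv(dy, self.w)
        self.grads[0][...] = _ConvCore.conv_backward_weight(x, cols)
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        super().__init__()
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads[0][...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        sum_dy = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g * (dy - sum_dy / n - xhat * sum_dy_xhat / n)


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 scale: float | None = None, dtype=np.float64):
        super().__init__()
        if scale is None:
            scale = math.sqrt(2.0 / nin)
        self.w = (rng.standard_normal((nin, nout)) * scale).astype(dtype)
        self.b = np.zeros(nout, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        for lyr in layers:
            self.params.extend(lyr.params)
            self.grads.extend(lyr.grads)

    def forward(self, x, train=True):
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x

    def backward(self, dy):
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy


class Adam:
    """Adam with linear warmup followed by a cosine decay of the peak rate."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 0.01, total_steps: int = 1000,
                 warmup_steps: int = 100, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr_max = lr
        self.total_steps = max(1, total_steps)
        self.warmup_steps = warmup_steps
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def learning_rate(self, step: int) -> float:
        if self.warmup_steps > 0 and step < self.warmup_steps:
            return self.lr_max * (step + 1) / self.warmup_steps
        span = max(1, self.total_steps - self.warmup_steps)
        frac = min(1.0, (step - self.warmup_steps) / span)
        return self.lr_max * 0.5 * (1.0 + math.cos(math.pi * frac))

    def step(self):
        lr = self.learning_rate(self.t)
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
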