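"""NumPy neural-network layers with explicit forward/backward passes.

All layers operate on ``float64`` arrays shaped ``[batch, maps, height, time]``
(the EEG convention: height is the electrode axis).  Each layer caches what its
backward pass needs; gradients accumulate into ``Param.grad``.  Convolutions
are bias-free — batch normalization (2 trainable parameters per feature map)
supplies the offset, which is the only reading consistent with the compact
architecture's parameter table.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "Param", "Layer", "Sequential", "TemporalConv", "DepthwiseSpatialConv",
    "SeparableConv", "BatchNorm", "ELU", "AvgPool", "Dropout", "Dense",
    "Flatten", "softmax", "softmax_cross_entropy",
]


class Param:
    """A learnable (or bookkept) array with its gradient accumulator."""

    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer: subclasses implement forward/backward."""

    def __init__(self):
        self.params: list[Param] = []

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)
        for lay in self.layers:
            self.params.extend(lay.params)

    def forward(self, x, training=False, rng=None):
        for lay in self.layers:
            x = lay.forward(x, training=training, rng=rng)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


def _same_pad(k: int):
    left = (k - 1) // 2
    return left, k - 1 - left


class TemporalConv(Layer):
    """Shared 1-D temporal filters: ``[B,1,C,T] -> [B,F,C,T]`` (same padding)."""

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (kernel + kernel * n_filters))
        self.w = Param(rng.uniform(-limit, limit, size=(n_filters, kernel)),
                       "temporal_conv.w")
        self.params = [self.w]
        self.kernel = kernel

    def forward(self, x, training=False, rng=None):
        left, right = _same_pad(self.kernel)
        xp = np.pad(x, [(0, 0), (0, 0), (0, 0), (left, right)])
        self._xp = xp
        w = self.w.value[None, :, None, :]
        # correlation = convolution with a time-reversed kernel
        return fftconvolve(xp, w[..., ::-1], mode="valid", axes=3)

    def backward(self, g):
        w = self.w.value[None, :, None, :]
        dxp = fftconvolve(g, w, mode="full", axes=3).sum(axis=1, keepdims=True)
        dw = fftconvolve(self._xp, g[..., ::-1], mode="valid", axes=3)
        self.w.grad += dw.sum(axis=(0, 2))
        left, right = _same_pad(self.kernel)
        T = dxp.shape[-1] - left - right
        return dxp[..., left:left + T]


class DepthwiseSpatialConv(Layer):
    """Per-map spatial filters over all electrodes: ``[B,F,C,T] -> [B,F*D,1,T]``."""

    def __init__(self, n_maps: int, depth: int, n_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_channels + n_channels * depth))
        self.w = Param(
            rng.uniform(-limit, limit, size=(n_maps, depth, n_channels)),
            "depthwise_conv.w",
        )
        self.params = [self.w]
        self.n_maps, self.depth = n_maps, depth

    def forward(self, x, training=False, rng=None):
        self._x = x
        y = np.einsum("bfct,fdc->bfdt", x, self.w.value)
        b, f, d, t = y.shape
        return y.reshape(b, f * d, 1, t)

    def backward(self, g):
        b = g.shape[0]
        g4 = g.reshape(b, self.n_maps, self.depth, g.shape[-1])
        self.w.grad += np.einsum("bfdt,bfct->fdc", g4, self._x)
        return np.einsum("bfdt,fdc->bfct", g4, self.w.value)


class SeparableConv(Layer):
    """Depthwise temporal conv + pointwise mix: ``[B,Fin,1,T] -> [B,F2,1,T]``."""

    def __init__(self, n_in: int, n_out: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        lim_d = np.sqrt(6.0 / (2 * kernel))
        lim_p = np.sqrt(6.0 / (n_in + n_out))
        self.dw = Param(rng.uniform(-lim_d, lim_d, size=(n_in, kernel)),
                        "separable_conv.depthwise")
        self.pw = Param(rng.uniform(-lim_p, lim_p, size=(n_out, n_in)),
                        "separable_conv.pointwise")
        self.params = [self.dw, self.pw]
        self.kernel = kernel

    def forward(self, x, training=False, rng=None):
        left, right = _same_pad(self.kernel)
        xp = np.pad(x, [(0, 0), (0, 0), (0, 0), (left, right)])
        self._xp = xp
        w = self.dw.value[None, :, None, :]
        ydw = fftconvolve(xp, w[..., ::-1], mode="valid", axes=3)
        self._ydw = ydw
        return np.einsum("bfot,gf->bgot", ydw, self.pw.value)

    def backward(self, g):
        self.pw.grad += np.einsum("bgot,bfot->gf", g, self._ydw)
        gdw = np.einsum("bgot,gf->bfot", g, self.pw.value)
        w = self.dw.value[None, :, None, :]
        dxp = fftconvolve(gdw, w, mode="full", axes=3)
        self.dw.grad += fftconvolve(
            self._xp, gdw[..., ::-1], mode="valid", axes=3
        ).sum(axis=(0, 2))
        left, right = _same_pad(self.kernel)
        T = dxp.shape[-1] - left - right
        return dxp[..., left:left + T]


class BatchNorm(Layer):
    """Per-feature-map normalization over (batch, space, time)."""

    def __init__(self, n_maps: int, eps: float = 1e-3, momentum: float = 0.1):
        super().__init__()
        self.gamma = Param(np.ones(n_maps), "batchnorm.gamma")
        self.beta = Param(np.zeros(n_maps), "batchnorm.beta")
        self.params = [self.gamma, self.beta]
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(n_maps)
        self.running_var = np.ones(n_maps)

    def forward(self, x, training=False, rng=None):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._xhat, self._std, self._training = xhat, std, training
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, g):
        axes = (0, 2, 3)
        xhat, std = self._xhat, self._std
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gam = self.gamma.value[None, :, None, None]
        if not self._training:
            return g * gam / std[None, :, None, None]
        n = g.shape[0] * g.shape[2] * g.shape[3]
        gsum = g.sum(axis=axes, keepdims=True)
        gx = (g * xhat).sum(axis=axes, keepdims=True)
        return (gam / std[None, :, None, None]) * (
            g - gsum / n - xhat * gx / n
        )


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._x, self._y = x, y
        return y

    def backward(self, g):
        return g * np.where(self._x > 0, 1.0, self._y + self.alpha)


class AvgPool(Layer):
    """Average pooling along time; a trailing remainder is truncated."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        p = self.pool
        t_out = x.shape[-1] // p
        self._t_in = x.shape[-1]
        xt = x[..., : t_out * p].reshape(x.shape[:-1] + (t_out, p))
        return xt.mean(axis=-1)

    def backward(self, g):
        p = self.pool
        gx = np.repeat(g[..., None], p, axis=-1).reshape(
            g.shape[:-1] + (g.shape[-1] * p,)
        ) / p
        if gx.shape[-1] < self._t_in:
            pad = self._t_in - gx.shape[-1]
            gx = np.pad(gx, [(0, 0)] * (gx.ndim - 1) + [(0, pad)])
        return gx


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = ((rng.random(x.shape) >= self.rate)
                      / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = Param(rng.uniform(-limit, limit, size=(n_out, n_in)), "dense.w")
        self.params = [self.w]
        self.b = None
        if bias:
            self.b = Param(np.zeros(n_out), "dense.b")
            self.params.append(self.b)

    def forward(self, x, training=False, rng=None):
        self._x = x
        y = x @ self.w.value.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, g):
        self.w.grad += g.T @ self._x
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        return g @ self.w.value


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n, probs
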