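"""Minimal channels-last (N, H, W, C) neural-network layers with explicit
forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad`` during ``backward``.
Convolution is evaluated as nine shifted matrix products against the
(kh, kw, Cin, Cout) kernel, which keeps memory low (only the padded input is
cached) and routes all heavy lifting through BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "MaxUnpool2d"]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Conv2d:
    """Same-padded stride-1 convolution with bias.

    Kernel shape (kh, kw, Cin, Cout); He-normal initialization.
    """

    def __init__(self, name: str, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = kernel * kernel * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel, kernel, in_ch, out_ch))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_ch))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.kernel
        p = k // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.empty((n, h, w, self.out_ch), dtype=np.float32)
        out[:] = self.bias.value
        wk = self.weight.value
        for i in range(k):
            for j in range(k):
                out += xp[:, i:i + h, j:j + w, :] @ wk[i, j]
        if training:
            self._xp = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward called before a training forward")
        k = self.kernel
        p = k // 2
        n, h, w, _ = dout.shape
        xp = self._xp
        wk = self.weight.value
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + h, j:j + w, :]
                self.weight.grad[i, j] += np.tensordot(
                    patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i:i + h, j:j + w, :] += dout @ wk[i, j].T
        self.bias.grad += dout.sum(axis=(0, 1, 2))
        self._xp = None
        return dxp[:, p:p + h, p:p + w, :]


class BatchNorm2d:
    """Batch normalization over (N, H, W) per channel, with affine params."""

    def __init__(self, name: str, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 1, 2)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        if training:
            self._cache = (xhat, invstd.astype(np.float32))
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before a training forward")
        xhat, invstd = self._cache
        axes = (0, 1, 2)
        m = float(np.prod([dout.shape[a] for a in axes]))
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        dx = (invstd / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes)
        )
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called before a training forward")
        dx = dout * self._mask
        self._mask = None
        return dx


def _window_view(x: np.ndarray, pool: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H/p, W/p, C, p*p) with windows flattened row-major."""
    n, h, w, c = x.shape
    hp, wp = h // pool, w // pool
    xr = x.reshape(n, hp, pool, wp, pool, c)
    return xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, hp, wp, c, pool * pool)


def _window_unview(d: np.ndarray, pool: int) -> np.ndarray:
    n, hp, wp, c, _ = d.shape
    dr = d.reshape(n, hp, wp, c, pool, pool)
    return dr.transpose(0, 1, 4, 2, 5, 3).reshape(n, hp * pool, wp * pool, c)


class MaxPool2d:
    """Non-overlapping max pooling that records per-window argmax positions.

    Ties break to the first occurrence in row-major scan order of the window.
    """

    def __init__(self, pool: int = 2):
        self.pool = pool
        self.indices: np.ndarray | None = None  # in-window positions, int8

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % self.pool or w % self.pool:
            raise ValueError(
                f"spatial size ({h}, {w}) not divisible by pool {self.pool}")
        xw = _window_view(x, self.pool)
        idx = xw.argmax(axis=4)
        out = np.take_along_axis(xw, idx[..., None], axis=4)[..., 0]
        self.indices = idx.astype(np.int8)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.indices is None:
            raise RuntimeError("backward called before forward")
        d4 = np.zeros(dout.shape + (self.pool * self.pool,), dtype=np.float32)
        np.put_along_axis(d4, self.indices[..., None].astype(np.int64),
                          dout[..., None], axis=4)
        return _window_unview(d4, self.pool)


class MaxUnpool2d:
    """Places each value at its recorded argmax position, zero elsewhere.

    Consumes the ``indices`` recorded by the counterpart :class:`MaxPool2d`.
    """

    def __init__(self, pool: int = 2):
        self.pool = pool
        self._idx: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, indices: np.ndarray,
                training: bool = False) -> np.ndarray:
        if indices.shape != x.shape:
            raise ValueError(
                f"indices shape {indices.shape} does not match input {x.shape}")
        x4 = np.zeros(x.shape + (self.pool * self.pool,), dtype=np.float32)
        np.put_along_axis(x4, indices[..., None].astype(np.int64),
                          x[..., None], axis=4)
        self._idx = indices
        return _window_unview(x4, self.pool)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._idx is None:
            raise RuntimeError("backward called before forward")
        dw = _window_view(dout, self.pool)
        dx = np.take_along_axis(dw, self._idx[..., None].astype(np.int64),
                                axis=4)[..., 0]
        self._idx = None
        return np.ascontiguousarray(dx)
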