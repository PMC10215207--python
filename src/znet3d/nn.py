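"""Minimal NumPy layers for 3D convolutional networks.

Every layer implements ``forward(x, train)`` and ``backward(gy)``;
``backward`` returns the gradient with respect to the layer input and
accumulates parameter gradients in place.  Tensors are float32 with a
``(N, C, D, H, W)`` layout.  Convolutions are evaluated as a sum of 27
(or 1) GEMMs over kernel offsets, which keeps peak memory far below an
im2col formulation at the volume sizes used here.
"""

from __future__ import annotations

from typing import Iterator, List, Tuple

import numpy as np


class Parameter:
    """A trainable array paired with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    def parameters(self) -> Iterator[Parameter]:
        for value in vars(self).values():
            if isinstance(value, Parameter):
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _check_5d(x: np.ndarray) -> None:
    if x.ndim != 5:
        raise ValueError(f"expected (N, C, D, H, W) tensor, got ndim={x.ndim}")


class Conv3d(Module):
    """3D convolution, stride 1, 'same' padding (kernel 3) or pointwise (kernel 1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: np.random.Generator = None):
        if kernel_size not in (1, 3):
            raise ValueError("only kernel sizes 1 and 3 are supported")
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size ** 3
        std = np.sqrt(2.0 / fan_in)  # Kaiming for ReLU nets
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels) + (kernel_size,) * 3)
        )
        self.bias = Parameter(np.zeros(out_channels))
        self._x = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.padding
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _check_5d(x)
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        self._x = x if train else None
        n, c, d, h, w = x.shape
        k = self.kernel_size
        xp = self._pad(x)
        out = np.broadcast_to(
            self.bias.data.reshape(1, -1, 1, 1, 1), (n, self.out_channels, d, h, w)
        ).copy()
        yf = out.reshape(n, self.out_channels, -1)
        for a in range(k):
            for b in range(k):
                for cc in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, :, a:a + d, b:b + h, cc:cc + w]
                    ).reshape(n, c, -1)
                    yf += self.weight.data[:, :, a, b, cc] @ xs
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called without a cached forward pass")
        x = self._x
        self._x = None
        n, c, d, h, w = x.shape
        k = self.kernel_size
        p = self.padding
        gyf = np.ascontiguousarray(gy).reshape(n, self.out_channels, -1)
        self.bias.grad += gy.sum(axis=(0, 2, 3, 4))
        xp = self._pad(x)
        gxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                for cc in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, :, a:a + d, b:b + h, cc:cc + w]
                    ).reshape(n, c, -1)
                    self.weight.grad[:, :, a, b, cc] += np.tensordot(
                        gyf, xs, axes=([0, 2], [0, 2])
                    )
                    gs = self.weight.data[:, :, a, b, cc].T @ gyf  # (N, C, M)
                    gxp[:, :, a:a + d, b:b + h, cc:cc + w] += gs.reshape(n, c, d, h, w)
        if p:
            return np.ascontiguousarray(gxp[:, :, p:p + d, p:p + h, p:p + w])
        return gxp


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _check_5d(x)
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, -1, 1, 1, 1)) * invstd.reshape(1, -1, 1, 1, 1)
        xhat = xhat.astype(np.float32)
        if train:
            self._cache = (xhat, invstd.astype(np.float32))
        return self.gamma.data.reshape(1, -1, 1, 1, 1) * xhat + self.beta.data.reshape(
            1, -1, 1, 1, 1
        )

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a cached forward pass")
        xhat, invstd = self._cache
        self._cache = None
        n, c, d, h, w = gy.shape
        m = n * d * h * w
        self.beta.grad += gy.sum(axis=(0, 2, 3, 4))
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3, 4))
        gxhat = gy * self.gamma.data.reshape(1, -1, 1, 1, 1)
        s1 = gxhat.sum(axis=(0, 2, 3, 4), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3, 4), keepdims=True)
        gx = (invstd.reshape(1, -1, 1, 1, 1) / m) * (m * gxhat - s1 - xhat * s2)
        return gx.astype(np.float32)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = (x > 0.0) if train else None
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask
        self._mask = None
        return gx


class Sigmoid(Module):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        self._y = y if train else None
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._y * (1.0 - self._y)
        self._y = None
        return gx


class MaxPool3d(Module):
    """2x2x2 max pooling, stride 2; input spatial dims must be even."""

    def __init__(self):
        self._arg = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _check_5d(x)
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {(d, h, w)}")
        xw = (
            x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, d // 2, h // 2, w // 2, 8)
        )
        if train:
            self._arg = xw.argmax(axis=-1)
            self._shape = x.shape
        return xw.max(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._arg is None:
            raise RuntimeError("backward called without a cached forward pass")
        n, c, d, h, w = self._shape
        g = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(g, self._arg[..., None], gy[..., None].astype(np.float32), -1)
        self._arg = None
        self._shape = None
        return np.ascontiguousarray(
            g.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )


def _up_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Double one axis by linear interpolation (half-pixel convention)."""
    x = np.moveaxis(x, axis, -1)
    left = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    right = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=np.float32)
    out[..., 0::2] = 0.75 * x + 0.25 * left
    out[..., 1::2] = 0.75 * x + 0.25 * right
    return np.moveaxis(out, -1, axis)


def _up_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    """Exact transpose of :func:`_up_axis` (used for the backward pass)."""
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    gx = (0.75 * (ge + go)).astype(np.float32)
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 0] += 0.25 * ge[..., 0]
    gx[..., 1:] += 0.25 * go[..., :-1]
    gx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(gx, -1, axis)


class Upsample3d(Module):
    """Trilinear 2x upsampling along each spatial axis."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _check_5d(x)
        for axis in (2, 3, 4):
            x = _up_axis(x, axis)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for axis in (4, 3, 2):
            gy = _up_axis_adjoint(gy, axis)
        return np.ascontiguousarray(gy)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adaptive-moment-estimation optimizer."""

    def __init__(self, params: List[Parameter], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
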