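"""Numpy layers with hand-derived backward passes.

Tensors are channel-first single examples: (C, H, W) float32 (one protein
per batch, as in the training loop). Convolution uses im2col so the inner
loop is a single GEMM; backward scatters through the same column map.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "Dropout",
    "ResidualBlock",
    "Sequential",
    "Adam",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def set_training(self, mode: bool) -> None:
        self.training = mode


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, H*W) with zero 'same' padding."""
    c, h, w = x.shape
    p = k // 2
    xp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=x.dtype)
    xp[:, p:p + h, p:p + w] = x
    cols = np.empty((c, k * k, h * w), dtype=x.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[:, idx] = xp[:, di:di + h, dj:dj + w].reshape(c, h * w)
            idx += 1
    return cols.reshape(c * k * k, h * w)


def _col2im(dcols: np.ndarray, c: int, h: int, w: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add back to the padded image)."""
    p = k // 2
    dxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    dcols = dcols.reshape(c, k * k, h * w)
    idx = 0
    for di in range(k):
        for dj in range(k):
            dxp[:, di:di + h, dj:dj + w] += dcols[:, idx].reshape(c, h, w)
            idx += 1
    return dxp[:, p:p + h, p:p + w]


class Conv2d(Layer):
    """Same-padded 2-D convolution; He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None, name: str = "conv") -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel_size * kernel_size
        w = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(c_out), f"{name}.bias")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if self.k == 1:
            cols = x.reshape(c, h * w)
        else:
            cols = _im2col(x, self.k)
        self._cols, self._shape = cols, (c, h, w)
        out = self.weight.value @ cols + self.bias.value[:, None]
        return out.reshape(self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        dy_mat = dy.reshape(self.c_out, h * w)
        self.weight.grad += dy_mat @ self._cols.T
        self.bias.grad += dy_mat.sum(axis=1)
        dcols = self.weight.value.T @ dy_mat
        if self.k == 1:
            return dcols.reshape(c, h, w)
        return _col2im(dcols, c, h, w, self.k)


class InstanceNorm2d(Layer):
    """Per-channel normalization over the spatial grid, with affine scale."""

    def __init__(self, channels: int, eps: float = 1e-5, name: str = "inorm") -> None:
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta")
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = xhat.shape[1] * xhat.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma.value[:, None, None]
        # d/dx of (x - mu) / sqrt(var + eps) over the spatial mean/variance
        term1 = dxhat
        term2 = dxhat.mean(axis=(1, 2), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        return inv * (term1 - term2 - term3)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; active only in training mode, seeded via ``rng``."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def set_training(self, mode: bool) -> None:
        for layer in self.layers:
            layer.set_training(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """Basic block: conv-IN-ReLU-(dropout)-conv-IN, identity skip, ReLU."""

    def __init__(self, channels: int, kernel_size: int = 3, dropout: float = 0.0,
                 rng: np.random.Generator | None = None, name: str = "block") -> None:
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(channels, channels, kernel_size, rng, f"{name}.conv1")
        self.in1 = InstanceNorm2d(channels, name=f"{name}.in1")
        self.relu1 = ReLU()
        self.drop = Dropout(dropout, rng) if dropout > 0 else None
        self.conv2 = Conv2d(channels, channels, kernel_size, rng, f"{name}.conv2")
        self.in2 = InstanceNorm2d(channels, name=f"{name}.in2")
        self.relu_out = ReLU()

    def parameters(self) -> list[Parameter]:
        out = self.conv1.parameters() + self.in1.parameters()
        out += self.conv2.parameters() + self.in2.parameters()
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for layer in (self.conv1, self.in1, self.relu1, self.conv2, self.in2, self.relu_out):
            layer.set_training(mode)
        if self.drop is not None:
            self.drop.set_training(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv1.forward(x)
        y = self.in1.forward(y)
        y = self.relu1.forward(y)
        if self.drop is not None:
            y = self.drop.forward(y)
        y = self.conv2.forward(y)
        y = self.in2.forward(y)
        return self.relu_out.forward(x + y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu_out.backward(dy)
        dres = self.in2.backward(dy)
        dres = self.conv2.backward(dres)
        if self.drop is not None:
            dres = self.drop.backward(dres)
        dres = self.relu1.backward(dres)
        dres = self.in1.backward(dres)
        dres = self.conv1.backward(dres)
        return dy + dres


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
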