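"""Minimal CPU neural-network layers with explicit forward/backward passes.

A small, dependency-free layer zoo sufficient for the fusion segmentation
network: 2D convolution (im2col + matmul), batch normalization, ReLU, 2x2 max
pooling, and a stride-matched transposed convolution (kernel size equal to
stride, i.e. each input pixel expands to an s x s learned patch — the
standard "deconvolution" upsampler without overlap).  Tensors are
``(batch, channels, height, width)`` float64 arrays; every layer implements
``forward(x)`` and ``backward(dout)`` and owns :class:`Param` objects that an
:class:`SGD` optimizer updates.  Parameters carry a ``trainable`` flag so
whole subnetworks can be frozen and later fine-tuned.

Determinism: all initialization draws from a generator supplied at
construction; with single-threaded BLAS, identical seeds give identical
training trajectories.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Upsample2d",
    "Sequential",
    "ResidualBlock",
    "SGD",
]


class Param:
    """A learnable tensor with gradient accumulator and freeze flag."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = True
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def training(self) -> bool:
        return getattr(self, "_training", True)

    def set_training(self, flag: bool) -> None:
        self._training = flag


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, H*W) patches for 'same' stride-1 convolution."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    b, c, h, w = x.shape
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, h * w)


class Conv2d(Layer):
    """Stride-1 'same' 2D convolution, k x k kernels."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization for ReLU nets
        self.k, self.cin, self.cout = k, cin, cout
        self.W = Param(rng.normal(0.0, scale, (cout, cin * k * k)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        b, c, h, w = x.shape
        self._cols = _im2col(x, self.k, self.k // 2)
        out = np.einsum("oc,bcp->bop", self.W.value, self._cols)
        return out.reshape(b, self.cout, h, w) + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, h, w = self._shape
        dflat = dout.reshape(b, self.cout, h * w)
        self.W.grad += np.einsum("bop,bcp->oc", dflat, self._cols)
        self.b.grad += dflat.sum(axis=(0, 2))
        # dx: full correlation with the flipped kernel == conv of dout with W^T rotated
        k = self.k
        Wt = self.W.value.reshape(self.cout, self.cin, k, k)
        Wr = Wt[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.cin, self.cout * k * k)
        cols = _im2col(dout, k, k // 2)
        dx = np.einsum("oc,bcp->bop", Wr, cols)
        return dx.reshape(self._shape)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = self.gamma.value[None, :, None, None]
        self.gamma.grad += (dout * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        if not self.training:
            return dout * g / self._std
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        return (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (requires even H, W)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        # route gradient to the first maximal element of each window
        eq = xr == out[:, :, :, None, :, None]
        flat = eq.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        first = flat.argmax(axis=-1)
        sel = np.zeros_like(flat, dtype=bool)
        np.put_along_axis(sel, first[..., None], True, axis=-1)
        self._sel = sel.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (self._sel * dout[:, :, :, None, :, None]).reshape(self._shape)


class Upsample2d(Layer):
    """Learned transposed convolution with kernel size equal to stride.

    Each input pixel maps to a non-overlapping s x s output patch; this is
    the exact adjoint of an s x s average/strided convolution and keeps the
    upsampling path fast and artifact-free.
    """

    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator | None = None, name: str = "up"):
        rng = rng or np.random.default_rng()
        self.s, self.cin, self.cout = stride, cin, cout
        scale = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, scale, (cin, cout, stride, stride)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        b, c, h, w = x.shape
        out = np.einsum("bcij,cdpq->bdipjq", x, self.W.value)
        return out.reshape(b, self.cout, h * self.s, w * self.s) + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, hs, ws = dout.shape
        s = self.s
        d6 = dout.reshape(b, self.cout, hs // s, s, ws // s, s).transpose(0, 1, 2, 4, 3, 5)
        # d6: (b, d, i, j, p, q)
        self.W.grad += np.einsum("bcij,bdijpq->cdpq", self._x, d6)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("bdijpq,cdpq->bcij", d6, self.W.value)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def set_training(self, flag: bool) -> None:
        for l in self.layers:
            l.set_training(flag)


class ResidualBlock(Layer):
    """Identity-shortcut block: y = x + F(x), F = n_layers x (conv-BN-ReLU).

    With all convolution weights (and BN shifts) at zero the block is an exact
    identity map — the property that makes deep stacks of these trainable.
    """

    def __init__(self, channels: int, n_layers: int = 4, k: int = 3,
                 rng: np.random.Generator | None = None, name: str = "res"):
        body = []
        for i in range(n_layers):
            body += [
                Conv2d(channels, channels, k, rng, f"{name}.conv{i}"),
                BatchNorm2d(channels, name=f"{name}.bn{i}"),
                ReLU(),
            ]
        self.body = Sequential(*body)

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout + self.body.backward(dout)

    def set_training(self, flag: bool) -> None:
        self.body.set_training(flag)


class SGD:
    """Stochastic gradient descent with classical momentum.

    Updates only parameters whose ``trainable`` flag is set; velocity of a
    frozen parameter is left untouched so freezing is side-effect free.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if not p.trainable:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
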