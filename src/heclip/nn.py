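"""Minimal neural-network core: layers with explicit forward/backward passes.

Everything runs on the CPU in float32 via numpy; convolutions use im2col so
the heavy lifting is BLAS matrix multiplication. Each layer caches what its
backward pass needs; ``backward`` consumes the upstream gradient, accumulates
parameter gradients in-place, and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

DTYPE = np.float32

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: subclasses define forward/backward and expose params."""

    training: bool = False

    def named_params(self, prefix: str = "") -> Iterable[tuple[str, Param]]:
        for name, attr in vars(self).items():
            if isinstance(attr, Param):
                yield f"{prefix}{name}", attr
            elif isinstance(attr, Module):
                yield from attr.named_params(f"{prefix}{name}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_params(f"{prefix}{name}.{i}.")

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.set_training(flag)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def zero_grad(self) -> None:
        for _, p in self.named_params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_params())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.value.shape}")
            p.value = arr.copy()
            p.grad = np.zeros_like(p.value)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        # He-style fan-in init keeps activations O(1) through GELU/ReLU
        scale = math.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value.T


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0)


class GELU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        return x * self._cdf

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return gout * (self._cdf + x * pdf)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(d))
        self.beta = Param(np.zeros(d))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.gamma.value + self.beta.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        d = xhat.shape[-1]
        self.gamma.grad += (gout * xhat).sum(axis=0)
        self.beta.grad += gout.sum(axis=0)
        gxhat = gout * self.gamma.value
        return inv / d * (
            d * gxhat
            - gxhat.sum(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
        )


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


class Conv2d(Module):
    """3x3-style convolution on NHWC arrays via im2col + matmul."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
    ):
        scale = math.sqrt(2.0 / (kernel * kernel * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(kernel * kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # N,Ho',Wo',C,k,k
        win = win[:, ::s, ::s]
        n, ho, wo = win.shape[0], win.shape[1], win.shape[2]
        # reorder to N,Ho,Wo,k,k,C so the flattened axis matches W's layout
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, ho, wo, -1)
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[3] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[3]}")
        p = self.padding
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._x_padded_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        n, ho, wo, _ = cols.shape
        out = cols.reshape(n * ho * wo, -1) @ self.W.value + self.b.value
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, ho, wo, _ = gout.shape
        gflat = gout.reshape(n * ho * wo, self.c_out)
        cols = self._cols.reshape(n * ho * wo, -1)
        self.W.grad += cols.T @ gflat
        self.b.grad += gflat.sum(axis=0)
        gcols = (gflat @ self.W.value.T).reshape(n, ho, wo, self.kernel, self.kernel, self.c_in)
        k, s, p = self.kernel, self.stride, self.padding
        gx = np.zeros(self._x_padded_shape, dtype=gout.dtype)
        # scatter-add each kernel offset back onto the (padded) input grid
        for di in range(k):
            for dj in range(k):
                gx[:, di : di + ho * s : s, dj : dj + wo * s : s, :] += gcols[:, :, :, di, dj, :]
        if p:
            gx = gx[:, p:-p, p:-p, :]
        return gx


class GlobalAvgPool(Module):
    """NHWC -> NC mean over the spatial grid."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        g = gout[:, None, None, :] / (h * w)
        return np.broadcast_to(g, self._shape).astype(gout.dtype)


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class Adam:
    """Adam with decoupled L2 weight decay on weight matrices."""

    def __init__(
        self,
        params: list[tuple[str, Param]],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for _, p in params]
        self.v = [np.zeros_like(p.value) for _, p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (name, p), m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and g.ndim > 1:  # decay weights, not biases/norm params
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad[...] = 0.0
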