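"""A compact numpy neural-network engine for the tile classifier.

Implements exactly what the training harness needs and nothing more:
3x3 same-padding convolutions, ReLU, 2x2 max pooling, dense layers, softmax
cross-entropy, and SGD with momentum. All computation is float32 numpy; a
fixed seed gives bit-reproducible training on a given platform.

Layers follow a minimal forward/backward protocol with parameters exposed as
``Param`` records so the optimizer and checkpointing stay trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrainingDivergedError

__all__ = [
    "Param",
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "cross_entropy",
    "SGDMomentum",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape-preserving).

    He-normal initialisation. Forward/backward are implemented as nine
    shifted tensor contractions, which is fast enough for 32-64 px tiles.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = Param((rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp
        out = np.zeros((N, self.w.value.shape[0], H, W), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                out += np.einsum(
                    "nchw,oc->nohw",
                    xp[:, :, di : di + H, dj : dj + W],
                    self.w.value[:, :, di, dj],
                    optimize=True,
                )
        return out + self.b.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        N, C, Hp, Wp = xp.shape
        H, W = Hp - 2, Wp - 2
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                self.w.grad[:, :, di, dj] = np.einsum(
                    "nohw,nchw->oc",
                    grad,
                    xp[:, :, di : di + H, dj : dj + W],
                    optimize=True,
                )
                dxp[:, :, di : di + H, dj : dj + W] += np.einsum(
                    "nohw,oc->nchw", grad, self.w.value[:, :, di, dj], optimize=True
                )
        self.b.grad[:] = grad.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even input sizes only)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        # Routing mask; on ties the gradient goes to every maximal entry.
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        g = self._mask * grad[:, :, :, None, :, None]
        return g.reshape(N, C, H, W).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param((rng.standard_normal((n_in, n_out)) * scale).astype(np.float32))
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad[:] = self._x.T @ grad
        self.b.grad[:] = grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state(self) -> list[np.ndarray]:
        """Snapshot of all parameter values (deep copies)."""
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite cross-entropy loss")
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGDMomentum:
    """Plain SGD with classical momentum: v <- m*v - lr*g; w <- w + v."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
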