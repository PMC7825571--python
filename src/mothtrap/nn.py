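"""A compact CPU neural-network engine for the moth classifier.

Implements exactly the pieces the customized CNN family needs — 'same'
padded 2-D convolution, ReLU, 2x2 stride-2 max pooling, dense layers,
inverted dropout, softmax cross-entropy, and Adam/SGD optimisers — on
float32 numpy arrays.  Convolutions are lowered to BLAS matrix products
via im2col; the data gradient is computed as a full convolution with the
spatially flipped kernels, so forward and backward passes are all gemm
calls.  Layouts are channels-last: activations are (B, H, W, C).

Everything is deterministic given the seed of the generator handed to
the layers that need randomness (initialisation, dropout).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "SGD",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, k*k*C) patch matrix for a 'same' convolution."""
    b, h, w, c = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    # windows: (B, H, W, C, k, k) -> (B, H, W, k, k, C)
    win = sliding_window_view(x, (k, k), axis=(1, 2))
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(b * h * w, k * k * c)


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> Optional[np.ndarray]:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """'same'-padded convolution with odd square kernels.

    ``first=True`` skips the input gradient (nothing upstream needs it),
    which saves the most expensive gemm of the whole backward pass.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 first: bool = False):
        super().__init__()
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("kernel size must be odd and positive")
        self.k, self.in_ch, self.out_ch, self.first = kernel, in_ch, out_ch, first
        fan_in = kernel * kernel * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.params = [w.astype(np.float32), np.zeros(out_ch, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    @property
    def n_params(self) -> int:
        return self.params[0].size + self.params[1].size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        cols = _im2col(x, self.k, self.k // 2)
        self._cols = cols if train else None
        b, h, w, _ = x.shape
        y = cols @ self.params[0] + self.params[1]
        return y.reshape(b, h, w, self.out_ch)

    def backward(self, dy: np.ndarray) -> Optional[np.ndarray]:
        b, h, w, _ = self._shape
        dy2 = dy.reshape(b * h * w, self.out_ch)
        self.grads[0][...] = self._cols.T @ dy2
        self.grads[1][...] = dy2.sum(axis=0)
        self._cols = None
        if self.first:
            return None
        # data gradient = full conv of dy with 180deg-rotated, channel-swapped kernels
        wk = self.params[0].reshape(self.k, self.k, self.in_ch, self.out_ch)
        wk = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(self.k * self.k * self.out_ch,
                                                          self.in_ch)
        cols = _im2col(dy, self.k, self.k // 2)
        return (cols @ wk).reshape(b, h, w, self.in_ch)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (dimensions must be even)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dimensions must be even for 2x2 pooling")
        self._shape = x.shape
        tiles = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        tiles = tiles.reshape(b, h // 2, w // 2, c, 4)
        self._arg = np.argmax(tiles, axis=-1)
        return np.take_along_axis(tiles, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        out = np.zeros((b, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return out.reshape(b, h, w, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w.astype(np.float32), np.zeros(n_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.params[0] + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.params[0].T


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Sequential:
    """A plain feed-forward stack with softmax-cross-entropy training."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    @property
    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        dy: Optional[np.ndarray] = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break

    def train_step(self, x: np.ndarray, labels: np.ndarray, optimizer: "Optimizer") -> float:
        logits = self.forward(x, train=True)
        loss, dlogits = softmax_cross_entropy(logits, labels)
        self.backward(dlogits)
        optimizer.step(self.params, self.grads)
        return loss

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def state_dict(self) -> dict:
        return {f"p{i}": p for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("state does not match model")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=p.dtype)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p[...] = arr


class Optimizer:
    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float = 0.01, momentum: float = 0.9):
        self.lr, self.momentum = lr, momentum
        self._v: Optional[List[np.ndarray]] = None

    def step(self, params, grads):
        if self._v is None:
            self._v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self._v):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: Optional[List[np.ndarray]] = None
        self._v: Optional[List[np.ndarray]] = None
        self._t = 0

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1c = 1 - self.beta1 ** self._t
        b2c = 1 - self.beta2 ** self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
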