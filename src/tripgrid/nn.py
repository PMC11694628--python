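"""Minimal feed-forward/convolutional network engine on numpy.

Provides exactly the pieces the classifier architectures need — Dense,
Conv2D (valid padding), MaxPool2x2, ReLU, Dropout, a Sequential container,
softmax cross-entropy, and Adam — with explicit reverse-mode gradients.
Everything is deterministic given the ``numpy.random.Generator`` supplied
at construction: weight init, dropout masks, and minibatch order all draw
from caller-provided generators.

Layout conventions: dense inputs are (N, D); image inputs are channels-last
(N, H, W, C), matching the (G, G, 1) occupancy-grid shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Dropout",
    "Conv2D",
    "MaxPool2x2",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Layer:
    """Base layer: forward caches what backward needs; params/grads parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        # He init, appropriate for the ReLU nonlinearities used throughout
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        b = np.zeros(out_dim)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.in_dim, self.out_dim = in_dim, out_dim

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.params[0].T

    def out_shape(self, in_shape):
        return (self.out_dim,)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Conv2D(Layer):
    """Valid (no padding) 2D convolution, stride 1, channels-last."""

    def __init__(
        self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        fan_in = kernel * kernel * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, in_ch, out_ch))
        b = np.zeros(out_ch)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.kernel, self.in_ch, self.out_ch = kernel, in_ch, out_ch

    def forward(self, x, train):
        k = self.kernel
        if x.shape[1] < k or x.shape[2] < k:
            raise ValueError(f"input spatial dims {x.shape[1:3]} smaller than kernel {k}")
        # patches: (N, H', W', C_in, k, k)
        patches = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        self._x_shape, self._patches = x.shape, patches
        out = np.einsum("nxycij,ijco->nxyo", patches, self.params[0])
        return out + self.params[1]

    def backward(self, grad):
        k = self.kernel
        self.grads[0][...] = np.einsum("nxycij,nxyo->ijco", self._patches, grad)
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        dx = np.zeros(self._x_shape)
        w = self.params[0]
        hp, wp = grad.shape[1], grad.shape[2]
        for i in range(k):
            for j in range(k):
                # each kernel tap contributes to a shifted window of dx
                dx[:, i : i + hp, j : j + wp, :] += np.einsum(
                    "nxyo,co->nxyc", grad, w[i, j]
                )
        return dx

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        return (h - self.kernel + 1, w - self.kernel + 1, self.out_ch)


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; identity when either spatial dim is < 2."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        if h < 2 or w < 2:
            self._identity = True
            return x
        self._identity = False
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        self._xc_shape, self._x_shape = xc.shape, x.shape
        out = xc.max(axis=(2, 4))
        self._argmask = xc == out[:, :, None, :, None, :]
        return out

    def backward(self, grad):
        if self._identity:
            return grad
        g = self._argmask * grad[:, :, None, :, None, :]
        # ties split the gradient evenly
        g = g / self._argmask.sum(axis=(2, 4), keepdims=True)
        dx = np.zeros(self._x_shape)
        n, h2, _, w2, _, c = self._xc_shape
        dx[:, : 2 * h2, : 2 * w2, :] = g.reshape(n, 2 * h2, 2 * w2, c)
        return dx

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if h < 2 or w < 2:
            return in_shape
        return (h // 2, w // 2, c)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [
            (p, g)
            for layer in self.layers
            for p, g in zip(layer.params, layer.grads)
        ]


class Adam:
    """Adam optimizer over (param, grad) pairs."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
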