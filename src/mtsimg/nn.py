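"""Minimal numpy layers for the convolutional classifiers.

Internal module: a small feed-forward stack (same-padded convolution via
im2col, 2x2/stride-2 max pooling, dense layers, softmax cross-entropy) with
mini-batch SGD + momentum.  float32 throughout; all randomness flows through
an explicit numpy Generator so training is replayable from a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer: forward caches whatever backward needs."""

    params: list  # list of (weight ref name) — see parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self):
        """Yield (param array, grad array) pairs, if any."""
        return ()


class Conv2D(Layer):
    """Same-padded 2-D convolution with odd square kernels.

    Weights are He-initialised and stored flattened as (filters, in_ch*k*k)
    so forward/backward are single matmuls against im2col patches.  Same
    padding keeps spatial dims unchanged — only pooling shrinks the map.
    """

    def __init__(self, in_ch: int, filters: int, kernel: int, rng: np.random.Generator):
        assert kernel % 2 == 1, "same padding requires an odd kernel"
        self.in_ch, self.filters, self.kernel = in_ch, filters, kernel
        fan_in = in_ch * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (filters, fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _im2col(self, xp: np.ndarray, H: int, W: int) -> np.ndarray:
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B, H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            xp.shape[0], H * W, self.in_ch * k * k
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._cols = self._im2col(xp, H, W)
        self._shape = (B, C, H, W)
        y = self._cols @ self.w.T + self.b
        return y.transpose(0, 2, 1).reshape(B, self.filters, H, W)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        k, p = self.kernel, self.kernel // 2
        g = grad.reshape(B, self.filters, H * W).transpose(0, 2, 1)  # (B, HW, F)
        self.dw = np.einsum("bpf,bpc->fc", g, self._cols, optimize=True)
        self.db = g.sum(axis=(0, 1))
        dcols = (g @ self.w).reshape(B, H, W, C, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, i, j]
        return dxp[:, :, p : p + H, p : p + W] if p else dxp

    def parameters(self):
        return ((self.w, self.dw, "w"), (self.b, self.db, "b"))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; halves both spatial dims exactly."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        assert H % 2 == 0 and W % 2 == 0, "pooling needs even spatial dims"
        self._x = x
        win = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = win.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._x.shape
        up_out = np.repeat(np.repeat(self._out, 2, axis=2), 2, axis=3)
        up_grad = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3)
        # ties route the gradient to every argmax in the window (deterministic)
        return np.where(self._x == up_out, up_grad, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim)).astype(
            np.float32
        )
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def parameters(self):
        return ((self.w, self.dw, "w"), (self.b, self.db, "b"))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over softmax outputs and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = np.finfo(np.float32).tiny
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Sequential:
    """A layer stack with SGD + momentum and weight snapshot/restore."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._velocity = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def sgd_step(self, lr: float, momentum: float = 0.9) -> None:
        for li, layer in enumerate(self.layers):
            for param, grad, tag in layer.parameters():
                key = (li, tag)
                v = self._velocity.get(key)
                if v is None:
                    v = np.zeros_like(param)
                v *= momentum
                v -= lr * grad
                param += v
                self._velocity[key] = v

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p, _, _ in layer.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p, _, _ in layer.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p, _, _ in layer.parameters()]
        assert len(flat) == len(weights)
        for p, w in zip(flat, weights):
            p[...] = w
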