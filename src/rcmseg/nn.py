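"""Minimal NumPy neural-network core: block convolutions, ReLU, pooling,
softmax cross-entropy and Adam.

All convolutions here have kernel size equal to their stride ("block
convolutions"), so every output cell is a function of one non-overlapping
input tile.  A stack of such layers with total stride S maps each aligned
S x S input block to exactly one feature vector, independently of the rest
of the image.  That property is what makes the fully-convolutional
expansion of the patch classifier exactly equivalent to sliding-window
patch inference (see :mod:`rcmseg.dense`).

Layers carry a dtype: float64 (the default) for bit-tight equivalence
checks, float32 for faster training at desk scale.  Arrays are NHWC.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Rescale",
    "BlockConv",
    "DepthwiseBlockConv",
    "PointwiseConv",
    "BatchNorm",
    "ReLU",
    "GlobalAvgPool",
    "Sequential",
    "softmax",
    "cross_entropy",
    "Adam",
]


def _blockify(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W, C) -> (B, H//k, W//k, k, k, C) non-overlapping tiles."""
    b, h, w, c = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {h}x{w} not divisible by block size {k}")
    x = x.reshape(b, h // k, k, w // k, k, c)
    return x.transpose(0, 1, 3, 2, 4, 5)


def _unblockify(blocks: np.ndarray) -> np.ndarray:
    b, ho, wo, k, k2, c = blocks.shape
    return blocks.transpose(0, 1, 3, 2, 4, 5).reshape(b, ho * k, wo * k2, c)


class Layer:
    """Base layer: parameters and their gradients live in parallel dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Rescale(Layer):
    """Affine input normalization y = x * scale + shift (no parameters)."""

    def __init__(self, scale: float = 1.0 / 255.0, shift: float = -0.4) -> None:
        super().__init__()
        self.scale = float(scale)
        self.shift = float(shift)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x * x.dtype.type(self.scale)
        y += x.dtype.type(self.shift)
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * g.dtype.type(self.scale)


class BlockConv(Layer):
    """Full convolution with kernel k and stride k (non-overlapping tiles)."""

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        self.k = k
        fan_in = k * k * c_in
        w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.params["w"] = w.astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        blocks = _blockify(x, self.k)
        b, ho, wo = blocks.shape[:3]
        cols = blocks.reshape(b, ho, wo, -1)
        self._cols = cols
        return cols @ self.params["w"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols = self._cols
        fan_in, c_out = self.params["w"].shape
        self.grads["w"] = cols.reshape(-1, fan_in).T @ g.reshape(-1, c_out)
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        dcols = g @ self.params["w"].T
        b, ho, wo = dcols.shape[:3]
        k = self.k
        c_in = fan_in // (k * k)
        return _unblockify(dcols.reshape(b, ho, wo, k, k, c_in))


class DepthwiseBlockConv(Layer):
    """Per-channel convolution with kernel k and stride k.

    For k == 1 this degenerates to a learnable per-channel scale, which keeps
    stride-1 stages structurally separable without mixing across tiles.
    """

    def __init__(self, k: int, channels: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        self.k = k
        w = rng.standard_normal((k, k, channels)) * np.sqrt(2.0 / (k * k))
        self.params["w"] = w.astype(dtype)
        self.params["b"] = np.zeros(channels, dtype)
        self._blocks: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        blocks = _blockify(x, self.k)
        self._blocks = blocks
        return np.einsum("bhwijc,ijc->bhwc", blocks, self.params["w"]) + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["w"] = np.einsum("bhwijc,bhwc->ijc", self._blocks, g)
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        dblocks = np.einsum("bhwc,ijc->bhwijc", g, self.params["w"])
        return _unblockify(dblocks)


class PointwiseConv(Layer):
    """1x1 convolution / dense layer over the trailing channel axis."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        w = rng.standard_normal((c_in, c_out)) * np.sqrt(2.0 / c_in)
        self.params["w"] = w.astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        c_in, c_out = self.params["w"].shape
        self.grads["w"] = self._x.reshape(-1, c_in).T @ g.reshape(-1, c_out)
        axes = tuple(range(g.ndim - 1))
        self.grads["b"] = g.sum(axis=axes)
        return g @ self.params["w"].T


class BatchNorm(Layer):
    """Per-channel batch normalization over the (batch, spatial) axes.

    ``training`` selects batch statistics (with running-average updates)
    versus stored running statistics.  In inference mode the layer is a
    fixed per-channel affine map, so it never mixes information across
    spatial positions and keeps the backbone's receptive fields
    block-aligned.
    """

    def __init__(self, channels: int, dtype=np.float64, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype)
        self.params["beta"] = np.zeros(channels, dtype)
        self.running_mean = np.zeros(channels, dtype)
        self.running_var = np.ones(channels, dtype)
        self.momentum = momentum
        self.eps = eps
        self.training = False
        self.calibrating = False
        self._calib_count = 0

    def start_calibration(self) -> None:
        """Reset running statistics for a fresh estimation sweep."""
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.ones_like(self.running_var)
        self._calib_count = 0
        self.calibrating = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self.calibrating:
                # cumulative (equal-weight) average over calibration batches
                self._calib_count += 1
                c = self._calib_count
                self.running_mean = self.running_mean + (mu - self.running_mean) / c
                if c == 1:
                    self.running_var = var.copy()
                else:
                    self.running_var = self.running_var + (var - self.running_var) / c
            else:
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mu
                self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = x - mu.astype(x.dtype)
        xhat *= inv
        self._cache = (xhat, inv, x.ndim)
        out = xhat * self.params["gamma"]
        out += self.params["beta"]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, ndim = self._cache
        axes = tuple(range(ndim - 1))
        gxhat_sum = (g * xhat).sum(axis=axes)
        g_sum = g.sum(axis=axes)
        self.grads["gamma"] = gxhat_sum
        self.grads["beta"] = g_sum
        scale = (self.params["gamma"] * inv).astype(g.dtype)
        if not self.training:
            return g * scale
        n = xhat.size // xhat.shape[-1]
        # dx = scale * (g - mean(g) - xhat * mean(g*xhat)); reuse the
        # cached xhat buffer, which is dead after this point.
        out = xhat
        out *= (-gxhat_sum / n).astype(g.dtype)
        out += g
        out -= (g_sum / n).astype(g.dtype)
        out *= scale
        self._cache = None
        return out


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class GlobalAvgPool(Layer):
    """(B, H, W, C) -> (B, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :], self._shape) / (h * w)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def set_training(self, training: bool) -> None:
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = training

    def named_params(self) -> list[tuple[str, Layer, str]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"{i}.{name}", layer, name))
        return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and the gradient w.r.t. the logits.

    ``probs`` is (B, K) softmax output, ``labels`` integer classes.
    """
    b = probs.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(b), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(b), labels] -= 1.0
    return float(loss), grad / b


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named_params: list[tuple[str, Layer, str]]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, name in named_params:
            g = layer.grads[name]
            m = self._m.setdefault(key, np.zeros_like(g))
            v = self._v.setdefault(key, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
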