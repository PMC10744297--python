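"""Minimal 1-D convolutional network engine (numpy, explicit backprop).

Implements exactly the layer vocabulary the spectral classifiers need —
Conv1D (same padding), ReLU, batch normalization, dropout, average pooling,
global average pooling, flatten, dense, residual blocks — plus Adam and
binary cross-entropy on logits.  Keras conventions are mostly followed (Glorot
uniform initialization, batch-norm eps 1e-3, Adam eps 1e-7) since those are
the defaults the architectures were designed around; batch-norm momentum is
0.9 rather than 0.99 so the inference-time running statistics converge within
the short training schedules these small spectral datasets get.

Tensors are ``(batch, channels, length)``.  Every layer caches what its
backward pass needs; :meth:`Sequential.backward` walks the layers in reverse
and can stop early, which is how Grad-CAM obtains the gradient of the logit
with respect to an intermediate feature map.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "ReLU",
    "BatchNorm1D",
    "Dropout",
    "AvgPool1D",
    "GlobalAvgPool1D",
    "Flatten",
    "Dense",
    "ResidualBlock1D",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.reshape(-1)
    y = targets.reshape(-1).astype(float)
    # softplus(z) - y*z, computed stably
    loss = float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.reshape(logits.shape)


class Layer:
    """Base layer: parameter dicts plus cached state for backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def l2_loss(self) -> float:
        return 0.0

    def sublayers(self) -> Iterable["Layer"]:
        return (self,)


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding and an L2 kernel penalty."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, l2: float = 1e-4):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.l2 = in_ch, out_ch, kernel, l2
        fan_in, fan_out = in_ch * kernel, out_ch * kernel
        self.params = {
            "W": _glorot_uniform(rng, (out_ch, in_ch, kernel), fan_in, fan_out),
            "b": np.zeros(out_ch),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k = self.kernel
        pad_l, pad_r = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, pad_r)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N, C, L, k)
        self._windows, self._xshape = windows, x.shape
        return np.einsum("nclk,fck->nfl", windows, self.params["W"], optimize=True) + self.params["b"][:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        self.grads["W"] = (
            np.einsum("nclk,nfl->fck", self._windows, grad, optimize=True) + 2.0 * self.l2 * W
        )
        self.grads["b"] = grad.sum(axis=(0, 2))
        n, c, L = self._xshape
        k = self.kernel
        pad_l = (k - 1) // 2
        dxp = np.zeros((n, c, L + k - 1))
        for kk in range(k):
            dxp[:, :, kk : kk + L] += np.einsum("nfl,fc->ncl", grad, W[:, :, kk], optimize=True)
        return dxp[:, :, pad_l : pad_l + L]

    def l2_loss(self) -> float:
        return self.l2 * float(np.sum(self.params["W"] ** 2))


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g, b = self.params["gamma"][:, None], self.params["beta"][:, None]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._training = training
        self._std = np.sqrt(var + self.eps)[:, None]
        self._xhat = (x - mean[:, None]) / self._std
        return g * self._xhat + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.params["gamma"][:, None]
        self.grads["gamma"] = (grad * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] = grad.sum(axis=(0, 2))
        dxhat = grad * g
        if not self._training:
            return dxhat / self._std
        m = grad.shape[0] * grad.shape[2]
        return (
            dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2), keepdims=True)
        ) / self._std


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class AvgPool1D(Layer):
    """Non-overlapping average pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, L = x.shape
        out_len = L // self.pool
        if out_len < 1:
            raise ValueError(f"input length {L} shorter than pool size {self.pool}")
        self._in_len = L
        return x[:, :, : out_len * self.pool].reshape(n, c, out_len, self.pool).mean(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, out_len = grad.shape
        dx = np.zeros((n, c, self._in_len))
        expanded = np.repeat(grad / self.pool, self.pool, axis=2)
        dx[:, :, : out_len * self.pool] = expanded
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._in_len, axis=2) / self._in_len


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, l2: float = 1e-4):
        super().__init__()
        self.l2 = l2
        self.params = {
            "W": _glorot_uniform(rng, (n_in, n_out), n_in, n_out),
            "b": np.zeros(n_out),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T

    def l2_loss(self) -> float:
        return self.l2 * float(np.sum(self.params["W"] ** 2))


class ResidualBlock1D(Layer):
    """conv-bn-relu-conv-bn with an additive shortcut, then ReLU.

    The shortcut is the identity when channel counts match, otherwise a 1x1
    convolution plus batch norm.  Zeroing the main path's weights makes the
    block the identity (up to the shortcut), the defining residual property.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, l2: float = 1e-4):
        super().__init__()
        self.main = [
            Conv1D(in_ch, out_ch, 3, rng, l2),
            BatchNorm1D(out_ch),
            ReLU(),
            Conv1D(out_ch, out_ch, 3, rng, l2),
            BatchNorm1D(out_ch),
        ]
        self.short: list[Layer] = []
        if in_ch != out_ch:
            self.short = [Conv1D(in_ch, out_ch, 1, rng, l2), BatchNorm1D(out_ch)]
        self.relu = ReLU()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for layer in self.main:
            h = layer.forward(h, training)
        s = x
        for layer in self.short:
            s = layer.forward(s, training)
        return self.relu.forward(h + s, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu.backward(grad)
        g_main = grad
        for layer in reversed(self.main):
            g_main = layer.backward(g_main)
        g_short = grad
        for layer in reversed(self.short):
            g_short = layer.backward(g_short)
        return g_main + g_short

    def l2_loss(self) -> float:
        return sum(l.l2_loss() for l in self.main + self.short)

    def sublayers(self) -> Iterable[Layer]:
        yield from self.main
        yield from self.short
        yield self.relu
        yield self


class Sequential:
    """A feed-forward stack with early-stopping backward for saliency hooks."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.layer_outputs: list[np.ndarray] | None = None

    def forward(self, x: np.ndarray, training: bool = False, record: bool = False) -> np.ndarray:
        outputs = []
        for layer in self.layers:
            x = layer.forward(x, training)
            if record:
                outputs.append(x)
        self.layer_outputs = outputs if record else None
        return x

    def backward(self, grad: np.ndarray, stop_after: int | None = None) -> np.ndarray:
        """Propagate ``grad`` backward; with ``stop_after=i`` return the
        gradient with respect to layer ``i``'s output without entering it."""
        for i in range(len(self.layers) - 1, -1, -1):
            if stop_after is not None and i == stop_after:
                return grad
            grad = self.layers[i].backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        out = []
        for layer in self.layers:
            for sub in layer.sublayers():
                for name in sub.params:
                    out.append((sub, name))
        return out

    def l2_loss(self) -> float:
        return sum(layer.l2_loss() for layer in self.layers)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2 and isinstance(self.layers[0], (Conv1D, ResidualBlock1D)):
            x = x[:, None, :]  # singleton channel axis for spectra matrices
        return self.forward(x, training=False).reshape(-1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.predict_logits(x))


class Adam:
    """Adam with Keras-style defaults (lr 1e-3, betas 0.9/0.999, eps 1e-7)."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.model, self.lr, self.beta1, self.beta2, self.eps = model, lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.model.parameters()):
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m.get(i, np.zeros_like(g))
            v = self.v.get(i, np.zeros_like(g))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.m[i], self.v[i] = m, v
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
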