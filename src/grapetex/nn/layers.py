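"""Minimal neural-network layers with explicit forward/backward passes.

Everything is plain numpy, float64, and deterministic given the generator
used at initialization. Each layer caches what its backward pass needs;
``backward`` must be called with the same batch that was last forwarded.

Conventions: images are ``(B, H, W, C)``; sequences are ``(B, T, F)``;
dense activations are ``(B, F)``.
"""

from __future__ import annotations

import numpy as np


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def describe(self) -> str:
        return type(self).__name__


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.in_features, self.units = in_features, units
        self.params = {
            "W": _glorot_uniform(rng, (in_features, units), in_features, units),
            "b": np.zeros(units),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["W"].T

    def describe(self):
        return f"Dense({self.in_features} -> {self.units})"


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)

    def describe(self):
        return f"LeakyReLU(alpha={self.alpha})"


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def describe(self):
        return f"Dropout(rate={self.rate})"


class Conv2D(Layer):
    """3x3 (configurable) convolution, stride 1, 'same' zero padding."""

    def __init__(self, in_channels: int, filters: int, rng: np.random.Generator,
                 kernel: int = 3):
        super().__init__()
        self.in_channels, self.filters, self.kernel = in_channels, filters, kernel
        fan_in = kernel * kernel * in_channels
        self.params = {
            "W": _glorot_uniform(
                rng, (kernel, kernel, in_channels, filters), fan_in, filters
            ),
            "b": np.zeros(filters),
        }

    def _im2col(self, x):
        k = self.kernel
        p = k // 2
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((b, h, w, k, k, c))
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = xp[:, i : i + h, j : j + w, :]
        return cols.reshape(b * h * w, k * k * c)

    def forward(self, x, training=False):
        self._xshape = x.shape
        b, h, w, c = x.shape
        self._cols = self._im2col(x)
        Wm = self.params["W"].reshape(-1, self.filters)
        out = self._cols @ Wm + self.params["b"]
        return out.reshape(b, h, w, self.filters)

    def backward(self, grad):
        b, h, w, c = self._xshape
        k = self.kernel
        p = k // 2
        g = grad.reshape(-1, self.filters)
        Wm = self.params["W"].reshape(-1, self.filters)
        self.grads = {
            "W": (self._cols.T @ g).reshape(self.params["W"].shape),
            "b": g.sum(axis=0),
        }
        dcols = (g @ Wm.T).reshape(b, h, w, k, k, c)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]

    def describe(self):
        return f"Conv2D({self.in_channels} -> {self.filters}, {self.kernel}x{self.kernel}, same)"


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2, 'valid' (trailing odd row/col dropped)."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        p = self.pool
        b, h, w, c = x.shape
        h2, w2 = h // p, w // p
        self._xshape = x.shape
        xt = x[:, : h2 * p, : w2 * p, :]
        xt = xt.reshape(b, h2, p, w2, p, c).transpose(0, 1, 3, 2, 4, 5)
        self._windows = xt.reshape(b, h2, w2, p * p, c)
        self._argmax = self._windows.argmax(axis=3)
        return np.take_along_axis(
            self._windows, self._argmax[:, :, :, None, :], axis=3
        )[:, :, :, 0, :]

    def backward(self, grad):
        p = self.pool
        b, h, w, c = self._xshape
        h2, w2 = h // p, w // p
        dwin = np.zeros_like(self._windows)
        np.put_along_axis(
            dwin, self._argmax[:, :, :, None, :], grad[:, :, :, None, :], axis=3
        )
        dx = np.zeros((b, h, w, c))
        dx[:, : h2 * p, : w2 * p, :] = (
            dwin.reshape(b, h2, w2, p, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h2 * p, w2 * p, c)
        )
        return dx

    def describe(self):
        return f"MaxPool2D({self.pool}x{self.pool})"


class BatchNorm(Layer):
    """Channel-wise batch normalization (last axis), Keras-style defaults."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = np.prod([x.shape[a] for a in axes])
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes = self._axes
        self.grads = {
            "gamma": (grad * self._xhat).sum(axis=axes),
            "beta": grad.sum(axis=axes),
        }
        g = grad * self.params["gamma"]
        if not self._training:
            return g * self._inv_std
        m = self._m
        return (
            self._inv_std
            / m
            * (
                m * g
                - g.sum(axis=axes)
                - self._xhat * (g * self._xhat).sum(axis=axes)
            )
        )

    def describe(self):
        return f"BatchNorm({self.channels})"


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Single LSTM layer over ``(B, T, F)``, returning the final hidden state.

    Gate order in the packed weight matrices is (input, forget, candidate,
    output); the forget-gate bias is initialized to 1. Parameter count is
    ``4 * (u * (u + F) + u)`` for ``u`` units and ``F`` input features.
    """

    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.in_features, self.units = in_features, units
        u = units
        b = np.zeros(4 * u)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.params = {
            "W": _glorot_uniform(rng, (in_features, 4 * u), in_features, u),
            "U": _glorot_uniform(rng, (u, 4 * u), u, u),
            "b": b,
        }

    def forward(self, x, training=False):
        B, T, F = x.shape
        u = self.units
        W, U, bias = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t, :] @ W + h @ U + bias
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        return h

    def backward(self, grad):
        x = self._x
        B, T, F = x.shape
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh, dc = grad, np.zeros((B, u))
        for t in reversed(range(T)):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ W.T
            dh = dz @ U.T
            dc = dc * f
        self.grads = {"W": dW, "U": dU, "b": db}
        return dx

    def describe(self):
        return f"LSTM({self.in_features} -> {self.units})"


class GlobalAveragePool2D(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        b, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :], self._shape) / (h * w)
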