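"""Minimal numpy neural-network core used by both pathways.

Implements exactly the layer set the two pathways need — im2col
convolution, max-pooling, fully connected layers, batch normalization,
ReLU — together with a sigmoid/binary-cross-entropy head and the Adam
optimizer.  Everything runs in float32 on a single CPU core; gradients
are computed by explicit backpropagation.

The sigmoid is folded into the loss (``sigmoid_bce_with_logits``) for
numerical stability; ``Sequential.predict`` applies it explicitly so
user-facing outputs are probabilities in [0, 1].
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv2d(Layer):
    """Same-padding 2D convolution via im2col (stride 1)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(c_in * k * k, c_out)))
        self.b = Param(np.zeros(c_out))

    def _im2col(self, x):
        # x: (N, C, H, W) padded -> (N*H*W, C*k*k)
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        n, c, h, w = win.shape[0], win.shape[1], win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        return np.ascontiguousarray(cols), (n, h, w)

    def forward(self, x, train):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xshape = x.shape
        cols, (n, h, w) = self._im2col(xp)
        self._cols = cols
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.W.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        gcols = g @ self.W.value.T  # (N*H*W, C*k*k)
        k, p = self.k, self.pad
        gcols = gcols.reshape(n, h, w, self.c_in, k, k)
        gx = np.zeros((n, self.c_in, h + 2 * p, w + 2 * p), dtype=np.float32)
        # scatter-add each kernel tap; k*k python iterations only
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gx[:, :, p:p + h, p:p + w]

    def params(self):
        return [self.W, self.b]


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling (truncates odd trailing rows/cols)."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train):
        k = self.k
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        self._xshape = x.shape
        xv = x[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
        self._arg = xv.argmax(axis=-1)
        return xv.max(axis=-1)

    def backward(self, grad):
        k = self.k
        n, c, h, w = self._xshape
        ho, wo = h // k, w // k
        gx = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
        np.put_along_axis(gx, self._arg[..., None], grad[..., None], axis=-1)
        gx = gx.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        out = np.zeros((n, c, h, w), dtype=np.float32)
        out[:, :, :ho * k, :wo * k] = gx.reshape(n, c, ho * k, wo * k)
        return out


class BatchNorm1d(Layer):
    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n, dtype=np.float32)
        self.running_var = np.ones(n, dtype=np.float32)

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        n = grad.shape[0]
        self.gamma.grad += (grad * self._xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        gxhat = grad * self.gamma.value
        return (gxhat - gxhat.mean(axis=0)
                - self._xhat * (gxhat * self._xhat).mean(axis=0)) / self._std


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass in evaluation mode, sigmoid applied to logits."""
        return sigmoid(self.forward(x.astype(np.float32), train=False))

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                state[f"p{i}_{j}"] = p.value
            if isinstance(layer, BatchNorm1d):
                state[f"rm{i}"] = layer.running_mean
                state[f"rv{i}"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p.value[...] = state[f"p{i}_{j}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"rm{i}"]
                layer.running_var[...] = state[f"rv{i}"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy over all elements, gradient w.r.t. logits.

    Stable form: bce = max(z,0) - z*t + log(1+exp(-|z|)).
    """
    z, t = logits, targets.astype(np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = sigmoid(z)
    grad = (p - t) / z.size
    return float(loss.mean()), grad


def bernoulli_entropy(p: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Per-element entropy of Bernoulli(p) in nats (the BCE floor)."""
    q = np.clip(p, eps, 1 - eps)
    return -(q * np.log(q) + (1 - q) * np.log(1 - q))


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
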