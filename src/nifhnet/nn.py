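"""Minimal NumPy neural-network engine.

Implements exactly the layer types the NifH classifier needs — token
embedding, 1-D convolution, max-pooling, dense, batch normalisation,
dropout, ReLU and softmax — together with an Adam optimizer and a
mini-batch training loop with per-epoch loss/accuracy history.

Conventions
-----------
* Activations are ``float32`` by default; gradient-check tests may build
  layers in ``float64``.
* Every layer exposes ``forward(x, training, rng)`` and ``backward(grad)``
  and lists its parameters as ``(name, param, grad)`` triples; non-trainable
  state (batch-norm moving statistics) is excluded from the optimizer but
  counted by :func:`parameter_count` under the "total parameters" convention
  (4 x features per batch-norm layer).
* All randomness (initialisation, shuffling, dropout masks) flows through a
  single :class:`numpy.random.Generator`, so training is deterministic for a
  fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Softmax",
    "Dropout",
    "BatchNorm",
    "Embedding",
    "Conv1D",
    "MaxPool1D",
    "GlobalMaxPool1D",
    "Sequential",
    "Adam",
    "cross_entropy",
    "fit",
]

_EPS = 1e-7


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class: a parameter-free, shape-preserving layer."""

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def params(self):
        return []

    def parameter_count(self) -> int:
        return sum(int(np.prod(p.shape)) for _, p, _ in self.params())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.w = _glorot(rng, n_in, n_out, (n_in, n_out), dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Softmax(Layer):
    """Row-wise softmax with the exact Jacobian-vector backward pass."""

    def forward(self, x, training=False, rng=None):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=-1, keepdims=True))


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate == 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class BatchNorm(Layer):
    """Batch normalisation over the leading (batch) axis.

    gamma/beta are trainable; moving mean/variance are tracked with
    exponential momentum and used at inference time.  The "total
    parameters" convention counts all four vectors (4 x features).
    """

    def __init__(self, n_features: int, momentum: float = 0.99, eps: float = 1e-3, dtype=np.float32):
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.moving_mean = np.zeros(n_features, dtype=dtype)
        self.moving_var = np.ones(n_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.moving_mean[...] = m * self.moving_mean + (1 - m) * mean
            self.moving_var[...] = m * self.moving_var + (1 - m) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        xhat = self._xhat
        self.dgamma[...] = (grad * xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        g = grad * self.gamma
        return (g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)) / self._std

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def parameter_count(self) -> int:
        # gamma + beta + moving mean + moving var
        return 4 * self.gamma.size

    def state(self):
        return {"moving_mean": self.moving_mean, "moving_var": self.moving_var}


class Embedding(Layer):
    """Token embedding with a frozen all-zero row for the padding token 0."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator, dtype=np.float32):
        self.w = rng.uniform(-0.05, 0.05, size=(vocab_size, dim)).astype(dtype)
        self.w[0] = 0.0
        self.dw = np.zeros_like(self.w)

    def forward(self, x, training=False, rng=None):
        self._tokens = x
        return self.w[x]

    def backward(self, grad):
        self.dw[...] = 0.0
        np.add.at(self.dw, self._tokens.reshape(-1), grad.reshape(-1, grad.shape[-1]))
        self.dw[0] = 0.0  # padding row stays non-informative
        return None  # integer input: no upstream gradient

    def params(self):
        return [("w", self.w, self.dw)]


class Conv1D(Layer):
    """Valid-mode 1-D convolution over (batch, time, channels) via im2col + GEMM."""

    def __init__(self, in_channels: int, out_channels: int, width: int,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = width * in_channels
        self.width = width
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = _glorot(rng, fan_in, out_channels, (fan_in, out_channels), dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @staticmethod
    def _im2col(x, width):
        # (batch, T, C) -> (batch, T-width+1, width*C)
        v = np.lib.stride_tricks.sliding_window_view(x, width, axis=1)
        # v: (batch, T-width+1, C, width) -> (batch, Tout, width, C)
        v = v.transpose(0, 1, 3, 2)
        b, t, w, c = v.shape
        return np.ascontiguousarray(v).reshape(b, t, w * c)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] < self.width:
            raise ValueError(
                f"input length {x.shape[1]} shorter than filter width {self.width}")
        self._cols = self._im2col(x, self.width)
        return self._cols @ self.w + self.b

    def backward(self, grad):
        b, t_out, f = grad.shape
        cols2d = self._cols.reshape(-1, self.w.shape[0])
        self.dw[...] = cols2d.T @ grad.reshape(-1, f)
        self.db[...] = grad.sum(axis=(0, 1))
        # full convolution of grad with the width-flipped filters gives dX
        pad = self.width - 1
        gpad = np.pad(grad, ((0, 0), (pad, pad), (0, 0)))
        gcols = self._im2col(gpad, self.width)  # (b, T, width*F)
        wflip = (self.w.reshape(self.width, self.in_channels, f)[::-1]
                 .transpose(0, 2, 1).reshape(self.width * f, self.in_channels))
        return gcols @ wflip

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class MaxPool1D(Layer):
    """Non-overlapping temporal max-pool; trailing remainder positions are dropped."""

    def __init__(self, size: int):
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size

    def forward(self, x, training=False, rng=None):
        b, t, c = x.shape
        n = t // self.size
        if n == 0:
            raise ValueError(f"input length {t} shorter than pool size {self.size}")
        xr = x[:, : n * self.size].reshape(b, n, self.size, c)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        b, n, c = grad.shape
        out = np.zeros(self._in_shape, dtype=grad.dtype)
        outr = out[:, : n * self.size].reshape(b, n, self.size, c)
        bi, ni, ci = np.ogrid[:b, :n, :c]
        outr[bi, ni, self._arg, ci] = grad
        return out


class GlobalMaxPool1D(Layer):
    """Max over the temporal axis: (batch, T, C) -> (batch, C)."""

    def forward(self, x, training=False, rng=None):
        self._arg = x.argmax(axis=1)
        self._in_shape = x.shape
        return x.max(axis=1)

    def backward(self, grad):
        b, t, c = self._in_shape
        out = np.zeros(self._in_shape, dtype=grad.dtype)
        bi, ci = np.ogrid[:b, :c]
        out[bi, self._arg, ci] = grad
        return out


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:  # reached an integer-input layer
                break
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def parameter_counts(self):
        """Total-parameter count per layer (batch-norm counts 4 x features)."""
        return [layer.parameter_count() for layer in self.layers]

    __call__ = forward


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in params]
        self.v = [np.zeros_like(p) for _, p, _ in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for (name, p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray):
    """Mean 2-class (or n-class) cross-entropy and its gradient w.r.t. probs."""
    n = probs.shape[0]
    p = np.clip(probs, _EPS, 1.0)
    loss = -(onehot * np.log(p)).sum() / n
    grad = -(onehot / p) / n
    return loss, grad.astype(probs.dtype)


def fit(model: Sequential, x: np.ndarray, y_onehot: np.ndarray, *, epochs: int,
        batch_size: int, lr: float, rng: np.random.Generator,
        shuffle: bool = True) -> dict:
    """Mini-batch Adam training; returns per-epoch ``loss`` and ``accuracy``.

    Raises RuntimeError with a learning-rate hint if the loss goes NaN.
    """
    n = x.shape[0]
    opt = Adam(model.params(), lr=lr)
    history = {"loss": [], "accuracy": []}
    for epoch in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y_onehot[idx]
            probs = model.forward(xb, training=True, rng=rng)
            loss, grad = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training loss is not finite; consider lowering the learning rate")
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
        history["loss"].append(float(epoch_loss / n))
        history["accuracy"].append(correct / n)
    return history
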