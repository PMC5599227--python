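"""Minimal NumPy neural-network engine: layers, Adam, seeded training.

Only what the classifier families need: dense layers, length-preserving
1-D convolution over time with full channel width, ReLU, kernel-2
max-pooling with floor division, inverted dropout, and softmax
cross-entropy.  All randomness (initialization, shuffling, dropout masks)
comes from generators seeded by the caller, so training is reproducible
bit for bit.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import DivergenceError


class Layer:
    """Base layer; parameters/gradients exposed as parallel lists."""

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


def _fan_in_uniform(rng, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(1.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        self.w = _fan_in_uniform(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.gw, self.gb]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Conv1dSame(Layer):
    """1-D convolution over time, filter width spanning all input channels.

    Input (batch, M, C); output (batch, M, F) via zero 'same' padding and
    stride 1 — each output row i is the dot product of the filter with the
    kernel-height window of rows around i.
    """

    def __init__(self, c_in: int, n_filters: int, kernel_size: int, rng):
        self.kernel_size = kernel_size
        self.c_in = c_in
        self.n_filters = n_filters
        fan_in = kernel_size * c_in
        self.w = _fan_in_uniform(rng, (fan_in, n_filters), fan_in)
        self.b = np.zeros(n_filters)

    @property
    def kernel(self) -> np.ndarray:
        """Weights reshaped to (kernel_size, channels, filters)."""
        return self.w.reshape(self.kernel_size, self.c_in, self.n_filters)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, m, c = x.shape
        lp = (self.kernel_size - 1) // 2
        rp = self.kernel_size - 1 - lp
        xp = np.pad(x, ((0, 0), (lp, rp), (0, 0)))
        cols = np.stack(
            [xp[:, i : i + m, :] for i in range(self.kernel_size)], axis=2
        )  # (b, m, k, c)
        return cols.reshape(b, m, self.kernel_size * c)

    def forward(self, x, train, rng):
        if x.ndim != 3 or x.shape[2] != self.c_in:
            raise ValueError(
                f"expected input (batch, time, {self.c_in}), got {x.shape}"
            )
        self._cols = self._im2col(x)
        self._in_shape = x.shape
        return self._cols @ self.w + self.b

    def backward(self, grad):
        b, m, c = self._in_shape
        k = self.kernel_size
        self.gw = self._cols.reshape(-1, k * c).T @ grad.reshape(-1, self.n_filters)
        self.gb = grad.sum(axis=(0, 1))
        gcols = (grad @ self.w.T).reshape(b, m, k, c)
        lp = (k - 1) // 2
        gxp = np.zeros((b, m + k - 1, c))
        for i in range(k):
            gxp[:, i : i + m, :] += gcols[:, :, i, :]
        return gxp[:, lp : lp + m, :]

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.gw, self.gb]


class MaxPool1d(Layer):
    """Non-overlapping temporal max; odd trailing rows are dropped (floor)."""

    def __init__(self, pool_size: int = 2):
        self.pool_size = pool_size

    def forward(self, x, train, rng):
        b, m, c = x.shape
        k = self.pool_size
        m_out = m // k
        windows = x[:, : m_out * k, :].reshape(b, m_out, k, c)
        self._argmax = windows.argmax(axis=2)
        self._in_shape = x.shape
        return windows.max(axis=2)

    def backward(self, grad):
        b, m, c = self._in_shape
        k = self.pool_size
        m_out = m // k
        gwin = np.zeros((b, m_out, k, c))
        np.put_along_axis(gwin, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        gx = np.zeros((b, m, c))
        gx[:, : m_out * k, :] = gwin.reshape(b, m_out * k, c)
        return gx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Network:
    """Plain sequential container with softmax cross-entropy on top."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y_idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.mean(np.log(probs[np.arange(n), y_idx] + 1e-300))
    grad = probs.copy()
    grad[np.arange(n), y_idx] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train_network(net: Network, x: np.ndarray, y_idx: np.ndarray,
                  config) -> list[float]:
    """Seeded mini-batch Adam training; returns per-epoch mean losses."""
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.parameters(), config.learning_rate,
               config.adam_beta1, config.adam_beta2, config.adam_eps)
    n = x.shape[0]
    history: list[float] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = net.forward(x[idx], train=True, rng=rng)
            loss, grad = softmax_cross_entropy(logits, y_idx[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            net.backward(grad)
            opt.step(net.gradients())
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return history
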