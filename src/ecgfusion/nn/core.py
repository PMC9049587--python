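"""Minimal 1-D neural-network layers with explicit forward/backward passes.

Everything is plain numpy; each layer caches what its backward pass
needs, accumulates parameter gradients in ``.grads``, and exposes
``(name, param, grad)`` triples through ``parameters()`` for the
optimizer.  Shapes follow the (batch, channels, length) convention for
convolutional layers and (batch, time, features) for the recurrent one.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless layers keep empty param dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def parameters(self):
        for name in self.params:
            yield name, self.params[name], self.grads[name]

    def zero_grads(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0


class Conv1D(Layer):
    """Valid 1-D convolution (cross-correlation), stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel))          # He init for ReLU nets
        self.params["W"] = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.params["b"] = np.zeros(c_out)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c_in, length = x.shape
        l_out = length - self.kernel + 1
        if l_out < 1:
            raise ValueError(
                f"input length {length} shorter than kernel {self.kernel}")
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        cols = cols.transpose(0, 2, 1, 3).reshape(b * l_out,
                                                  c_in * self.kernel)
        wf = self.params["W"].reshape(self.c_out, -1)
        y = cols @ wf.T + self.params["b"]
        self._cache = (cols, x.shape, l_out)
        return y.reshape(b, l_out, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, l_out = self._cache
        b, c_in, length = x_shape
        dyf = dy.transpose(0, 2, 1).reshape(b * l_out, self.c_out)
        self.grads["W"] += (dyf.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"].reshape(self.c_out, -1))
        dcols = dcols.reshape(b, l_out, c_in, self.kernel)
        dx = np.zeros(x_shape)
        for j in range(self.kernel):
            dx[:, :, j:j + l_out] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * ivar[None, :, None]
        self._cache = (xhat, ivar, x.shape[0] * x.shape[2])
        return (self.params["gamma"][None, :, None] * xhat
                + self.params["beta"][None, :, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, n = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] += dy.sum(axis=(0, 2))
        dxhat = dy * self.params["gamma"][None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (ivar[None, :, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder samples dropped."""

    def __init__(self, size: int) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, length = x.shape
        l_out = length // self.size
        xt = x[:, :, : l_out * self.size].reshape(b, c, l_out, self.size)
        self._argmax = xt.argmax(axis=3)
        self._x_shape = x.shape
        return xt.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, l_out = dy.shape
        dx = np.zeros((b, c, l_out, self.size))
        bi, ci, li = np.ogrid[:b, :c, :l_out]
        dx[bi, ci, li, self._argmax] = dy
        full = np.zeros(self._x_shape)
        full[:, :, : l_out * self.size] = dx.reshape(b, c, -1)
        return full


class GlobalAvgPool(Layer):
    """(batch, channels, length) -> (batch, channels) mean over length."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._length, axis=2) / self._length


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params["W"] = rng.normal(0.0, scale, size=(d_in, d_out))
        self.params["b"] = np.zeros(d_out)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, keep_prob: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 < keep_prob <= 1:
            raise ValueError("keep_prob must be in (0, 1]")
        self.keep_prob = keep_prob
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.keep_prob >= 1.0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) < self.keep_prob)
        return x * self._mask / self.keep_prob

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask / self.keep_prob


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTMCellStack(Layer):
    """Unidirectional LSTM over (batch, time, features) -> hidden states.

    Gate order in the packed weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at +1, the usual trick that
    keeps early gradients flowing through the cell state.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        s = 1.0 / np.sqrt(hidden)
        self.params["W"] = rng.uniform(-s, s, size=(d_in, 4 * hidden))
        self.params["U"] = rng.uniform(-s, s, size=(hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.params["b"] = b
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, t_steps, _ = x.shape
        h = np.zeros((b, self.hidden))
        c = np.zeros((b, self.hidden))
        hs = np.zeros((b, t_steps, self.hidden))
        cache = []
        hsz = self.hidden
        for t in range(t_steps):
            a = (x[:, t] @ self.params["W"] + h @ self.params["U"]
                 + self.params["b"])
            i = _sigmoid(a[:, :hsz])
            f = _sigmoid(a[:, hsz:2 * hsz])
            g = np.tanh(a[:, 2 * hsz:3 * hsz])
            o = _sigmoid(a[:, 3 * hsz:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache.append((x[:, t], i, f, g, o, c_prev, tc,
                          hs[:, t - 1] if t > 0 else np.zeros((b, hsz))))
        self._cache = (cache, x.shape)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cache, x_shape = self._cache
        b, t_steps, _ = x_shape
        hsz = self.hidden
        dx = np.zeros(x_shape)
        dh_next = np.zeros((b, hsz))
        dc_next = np.zeros((b, hsz))
        for t in reversed(range(t_steps)):
            xt, i, f, g, o, c_prev, tc, h_prev = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            self.grads["W"] += xt.T @ da
            self.grads["U"] += h_prev.T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, t] = da @ self.params["W"].T
            dh_next = da @ self.params["U"].T
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM returning the concatenated final hidden states.

    The forward pass reads the sequence left to right, the backward pass
    right to left; the representation of the whole sequence is the
    concatenation of the two final hidden states (forward (+) backward).
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fwd = LSTMCellStack(d_in, hidden, rng)
        self.bwd = LSTMCellStack(d_in, hidden, rng)
        self.hidden = hidden

    def parameters(self):
        for name, p, g in self.fwd.parameters():
            yield f"fwd.{name}", p, g
        for name, p, g in self.bwd.parameters():
            yield f"bwd.{name}", p, g

    def zero_grads(self) -> None:
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        hs_f = self.fwd.forward(x, train)
        hs_b = self.bwd.forward(x[:, ::-1], train)
        self._t = x.shape[1]
        return np.concatenate([hs_f[:, -1], hs_b[:, -1]], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b = dy.shape[0]
        dhs_f = np.zeros((b, self._t, self.hidden))
        dhs_b = np.zeros((b, self._t, self.hidden))
        dhs_f[:, -1] = dy[:, : self.hidden]
        dhs_b[:, -1] = dy[:, self.hidden:]
        dx = self.fwd.backward(dhs_f)
        dx += self.bwd.backward(dhs_b)[:, ::-1]
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n
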