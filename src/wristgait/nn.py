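"""Minimal 1-D convolutional network toolkit (numpy, explicit backprop).

Implements exactly what the desk-scale gait regressor needs: Conv1d via
im2col, BatchNorm1d, ReLU, residual blocks, global average pooling, linear
layers, dropout, an Adam optimizer and L1/BCE losses. All randomness flows
through a numpy Generator, so initialization, dropout and training are
bit-reproducible for a given seed.

Shapes: signals are (batch, channels, length); features are (batch, dim).
"""

from __future__ import annotations

import hashlib

import numpy as np

#: compute dtype for all parameters and activations; float32 keeps the
#: desk-scale training loop memory-bound ops fast, float64 is available for
#: verification (set before building a network)
DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: forward caches what backward needs; parameters() yields
    (name, Parameter) pairs of this module and its children."""

    #: names of non-trainable per-module state arrays (e.g. BN running stats)
    _buffer_names: tuple[str, ...] = ()

    def _walk(self):
        yield "", self
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                for sub, mod in attr._walk():
                    yield f"{name}.{sub}".rstrip("."), mod
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, mod in item._walk():
                            yield f"{name}.{i}.{sub}".rstrip("."), mod
            elif isinstance(attr, dict):
                for key, item in attr.items():
                    if isinstance(item, Module):
                        for sub, mod in item._walk():
                            yield f"{name}.{key}.{sub}".rstrip("."), mod

    def parameters(self):
        for prefix, mod in self._walk():
            for name, attr in vars(mod).items():
                if isinstance(attr, Parameter):
                    yield f"{prefix}.{name}".lstrip("."), attr

    def buffers(self):
        for prefix, mod in self._walk():
            for name in mod._buffer_names:
                yield f"{prefix}.{name}".lstrip("."), mod, name

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """All parameters plus buffers (BN running stats) — a full snapshot."""
        out = {name: p.value.copy() for name, p in self.parameters()}
        for name, mod, attr in self.buffers():
            out[f"buf:{name}"] = getattr(mod, attr).copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.parameters():
            p.value[...] = state[name]
        for name, mod, attr in self.buffers():
            key = f"buf:{name}"
            if key in state:
                setattr(mod, attr, state[key].copy())

    def checksum(self) -> str:
        """Hash of all parameter bytes (order-stable); detects any drift."""
        h = hashlib.sha256()
        for name, p in sorted(self.parameters(), key=lambda t: t[0]):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()


class Conv1d(Module):
    """Same-padded 1-D convolution with stride, via im2col + einsum."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int,
                 rng: np.random.Generator):
        self.k, self.stride = k, stride
        scale = np.sqrt(2.0 / (in_ch * k))  # He init
        self.w = Parameter(scale * rng.standard_normal((out_ch, in_ch, k)))
        self.b = Parameter(np.zeros(out_ch))
        self._cache = None

    def forward(self, x, train):
        B, C, L = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = cols[:, :, :: self.stride, :]  # (B, C, Lout, k)
        # keep only full output positions matching ceil(L/stride)
        L_out = (L + self.stride - 1) // self.stride
        cols = cols[:, :, :L_out, :]
        # gemm: (B*Lout, C*k) @ (C*k, O)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            B * L_out, C * self.k
        )
        w2 = self.w.value.reshape(self.w.value.shape[0], -1)  # (O, C*k)
        y = (cols2 @ w2.T).reshape(B, L_out, -1).transpose(0, 2, 1)
        y = y + self.b.value[None, :, None]
        self._cache = (cols2, x.shape, L_out)
        return y

    def backward(self, g):
        cols2, (B, C, L), L_out = self._cache
        O = g.shape[1]
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * L_out, O)
        self.w.grad += (g2.T @ cols2).reshape(self.w.value.shape)
        self.b.grad += g2.sum(axis=0)
        w2 = self.w.value.reshape(O, -1)
        gcols = (g2 @ w2).reshape(B, L_out, C, self.k).transpose(0, 2, 1, 3)
        p = self.k // 2
        gxp = np.zeros((B, C, L + 2 * p), dtype=gcols.dtype)
        for kk in range(self.k):
            gxp[:, :, kk : kk + self.stride * L_out : self.stride] += gcols[:, :, :, kk]
        return gxp[:, :, p : p + L]


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) per channel.

    ``frozen`` bypasses running-statistic updates and uses stored stats in
    both modes, so a frozen backbone stays bit-identical through training.
    """

    _buffer_names = ("run_mean", "run_var")

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.run_mean = np.zeros(ch, dtype=DTYPE)
        self.run_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.frozen = False
        self._cache = None

    def forward(self, x, train):
        if train and not self.frozen:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std, train and not self.frozen)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, g):
        xhat, std, batch_stats = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 2))
        self.beta.grad += g.sum(axis=(0, 2))
        gxhat = g * self.gamma.value[None, :, None]
        if not batch_stats:
            return gxhat / std[None, :, None]
        m = g.shape[0] * g.shape[2]
        mean_g = gxhat.mean(axis=(0, 2), keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return (gxhat - mean_g - xhat * mean_gx) / std[None, :, None]


class ReLU(Module):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class GlobalAvgPool(Module):
    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g):
        return np.repeat(g[:, :, None], self._L, axis=2) / self._L


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(scale * rng.standard_normal((n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class ResBlock(Module):
    """conv-BN-ReLU-conv-BN with identity (or 1x1-conv) shortcut, ReLU out."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int,
                 rng: np.random.Generator):
        self.branch = Sequential(
            Conv1d(in_ch, out_ch, k, stride, rng),
            BatchNorm1d(out_ch),
            ReLU(),
            Conv1d(out_ch, out_ch, k, 1, rng),
            BatchNorm1d(out_ch),
        )
        if in_ch != out_ch or stride != 1:
            self.shortcut = Sequential(
                Conv1d(in_ch, out_ch, 1, stride, rng), BatchNorm1d(out_ch)
            )
        else:
            self.shortcut = None
        self.relu = ReLU()

    def forward(self, x, train):
        b = self.branch.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu.forward(b + s, train)

    def backward(self, g):
        g = self.relu.backward(g)
        gb = self.branch.backward(g)
        gs = g if self.shortcut is None else self.shortcut.backward(g)
        return gb + gs


class Adam:
    """Adam over an explicit (name, Parameter) list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for _, p in self.params]
        self.v = [np.zeros_like(p.value) for _, p in self.params]
        self.t = 0

    def zero_grad(self):
        for _, p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for (name, p), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; numerically stable."""
    z, y = logits, target
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss), (p - y) / z.size
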