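"""Layers with explicit forward/backward passes.

Conventions: 1-D tensors are (batch, channels, time); 2-D tensors are
(batch, channels, height, width).  Every layer caches what it needs on
``forward`` and returns the gradient w.r.t. its input from ``backward``.
Parameters are held in :class:`Param` objects so optimizers can walk them.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int) -> None:
        self.n_in, self.n_out = n_in, n_out
        self.w = Param(np.zeros((n_in, n_out)), "dense.w")
        self.b = Param(np.zeros(n_out), "dense.b")

    def params(self):
        return [self.w, self.b]

    def initialize(self, rng):
        self.w.value = rng.normal(0.0, np.sqrt(2.0 / self.n_in), (self.n_in, self.n_out))
        self.b.value = np.zeros(self.n_out)

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Conv1d(Layer):
    """Dilated 1-D convolution.

    ``padding='causal'`` left-pads by (k-1)*dilation so the output at time t
    depends only on inputs at times <= t and the length is preserved —
    the padding scheme the temporal-convolution blocks rely on.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int = 1,
                 padding: str = "causal") -> None:
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.c_in, self.c_out = c_in, c_out
        self.k, self.d = kernel_size, dilation
        if padding not in ("causal", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.padding = padding
        self.w = Param(np.zeros((c_out, c_in, kernel_size)), "conv1d.w")
        self.b = Param(np.zeros(c_out), "conv1d.b")

    def params(self):
        return [self.w, self.b]

    def initialize(self, rng):
        fan_in = self.c_in * self.k
        self.w.value = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.w.value.shape)
        self.b.value = np.zeros(self.c_out)

    def forward(self, x):
        b, c, t = x.shape
        pad = (self.k - 1) * self.d if self.padding == "causal" else 0
        xp = np.pad(x, ((0, 0), (0, 0), (pad, 0)))
        t_out = t if self.padding == "causal" else t - (self.k - 1) * self.d
        self._xp, self._t_out = xp, t_out
        y = np.broadcast_to(self.b.value[None, :, None], (b, self.c_out, t_out)).copy()
        for i in range(self.k):
            seg = xp[:, :, i * self.d: i * self.d + t_out]
            y += np.einsum("oc,bct->bot", self.w.value[:, :, i], seg)
        return y

    def backward(self, grad):
        xp, t_out = self._xp, self._t_out
        gxp = np.zeros_like(xp)
        for i in range(self.k):
            seg = xp[:, :, i * self.d: i * self.d + t_out]
            self.w.grad[:, :, i] += np.einsum("bot,bct->oc", grad, seg)
            gxp[:, :, i * self.d: i * self.d + t_out] += np.einsum(
                "bot,oc->bct", grad, self.w.value[:, :, i])
        self.b.grad += grad.sum(axis=(0, 2))
        pad = (self.k - 1) * self.d if self.padding == "causal" else 0
        return gxp[:, :, pad:] if pad else gxp


class Conv2d(Layer):
    """2-D convolution with 'same' zero padding and integer stride."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int = 1) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s = kernel_size, stride
        self.w = Param(np.zeros((c_out, c_in, kernel_size, kernel_size)), "conv2d.w")
        self.b = Param(np.zeros(c_out), "conv2d.b")

    def params(self):
        return [self.w, self.b]

    def initialize(self, rng):
        fan_in = self.c_in * self.k * self.k
        self.w.value = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.w.value.shape)
        self.b.value = np.zeros(self.c_out)

    def _pad_amounts(self, h, w):
        # 'same' for stride s: out = ceil(in / s)
        ho = -(-h // self.s)
        wo = -(-w // self.s)
        ph = max((ho - 1) * self.s + self.k - h, 0)
        pw = max((wo - 1) * self.s + self.k - w, 0)
        return ho, wo, ph // 2, ph - ph // 2, pw // 2, pw - pw // 2

    def forward(self, x):
        b, c, h, w = x.shape
        ho, wo, pt, pb_, pl, pr = self._pad_amounts(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb_), (pl, pr)))
        self._xp, self._shape = xp, (h, w, ho, wo, pt, pl)
        y = np.broadcast_to(self.b.value[None, :, None, None], (b, self.c_out, ho, wo)).copy()
        for p in range(self.k):
            for q in range(self.k):
                seg = xp[:, :, p: p + self.s * ho: self.s, q: q + self.s * wo: self.s]
                y += np.einsum("oc,bcij->boij", self.w.value[:, :, p, q], seg)
        return y

    def backward(self, grad):
        xp = self._xp
        h, w, ho, wo, pt, pl = self._shape
        gxp = np.zeros_like(xp)
        for p in range(self.k):
            for q in range(self.k):
                seg = xp[:, :, p: p + self.s * ho: self.s, q: q + self.s * wo: self.s]
                self.w.grad[:, :, p, q] += np.einsum("boij,bcij->oc", grad, seg)
                gxp[:, :, p: p + self.s * ho: self.s, q: q + self.s * wo: self.s] += \
                    np.einsum("boij,oc->bcij", grad, self.w.value[:, :, p, q])
        self.b.grad += grad.sum(axis=(0, 2, 3))
        return gxp[:, :, pt: pt + h, pl: pl + w]


class DepthwiseConv2d(Layer):
    """Per-channel 2-D convolution ('same' padding), as used in
    depthwise-separable blocks."""

    def __init__(self, channels: int, kernel_size: int, stride: int = 1) -> None:
        self.c = channels
        self.k, self.s = kernel_size, stride
        self.w = Param(np.zeros((channels, kernel_size, kernel_size)), "dwconv.w")
        self.b = Param(np.zeros(channels), "dwconv.b")

    def params(self):
        return [self.w, self.b]

    def initialize(self, rng):
        fan_in = self.k * self.k
        self.w.value = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.w.value.shape)
        self.b.value = np.zeros(self.c)

    def forward(self, x):
        b, c, h, w = x.shape
        ho = -(-h // self.s)
        wo = -(-w // self.s)
        ph = max((ho - 1) * self.s + self.k - h, 0)
        pw = max((wo - 1) * self.s + self.k - w, 0)
        pt, pl = ph // 2, pw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pt, ph - pt), (pl, pw - pl)))
        self._xp, self._shape = xp, (h, w, ho, wo, pt, pl)
        y = np.broadcast_to(self.b.value[None, :, None, None], (b, c, ho, wo)).copy()
        for p in range(self.k):
            for q in range(self.k):
                seg = xp[:, :, p: p + self.s * ho: self.s, q: q + self.s * wo: self.s]
                y += self.w.value[None, :, p, q, None, None] * seg
        return y

    def backward(self, grad):
        xp = self._xp
        h, w, ho, wo, pt, pl = self._shape
        gxp = np.zeros_like(xp)
        for p in range(self.k):
            for q in range(self.k):
                seg = xp[:, :, p: p + self.s * ho: self.s, q: q + self.s * wo: self.s]
                self.w.grad[:, p, q] += np.einsum("bcij,bcij->c", grad, seg)
                gxp[:, :, p: p + self.s * ho: self.s, q: q + self.s * wo: self.s] += \
                    grad * self.w.value[None, :, p, q, None, None]
        self.b.grad += grad.sum(axis=(0, 2, 3))
        return gxp[:, :, pt: pt + h, pl: pl + w]


class AvgPool2d(Layer):
    """Non-overlapping average pooling; input H, W must be divisible by k."""

    def __init__(self, k: int) -> None:
        self.k = k

    def forward(self, x):
        b, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"AvgPool2d({k}): spatial dims {(h, w)} not divisible")
        self._in_shape = x.shape
        return x.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad):
        b, c, h, w = self._in_shape
        k = self.k
        g = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        return g


class GlobalAvgPool2d(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], self._in_shape) / (h * w)


class GlobalAvgPool1d(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=2)

    def backward(self, grad):
        b, c, t = self._in_shape
        return np.broadcast_to(grad[:, :, None], self._in_shape) / t


class Upsample1d(Layer):
    """Broadcast a (batch, features) vector across ``length`` time steps —
    the first stage of the latent-to-sequence decoder."""

    def __init__(self, length: int) -> None:
        self.length = length

    def forward(self, x):
        return np.broadcast_to(x[:, :, None], (*x.shape, self.length)).copy()

    def backward(self, grad):
        return grad.sum(axis=2)


class Residual(Layer):
    """y = f(x) + x (identity shortcut; channel counts must match)."""

    def __init__(self, inner: "Layer | list[Layer]") -> None:
        from .network import Sequential

        self.inner = inner if isinstance(inner, Layer) else Sequential(inner)

    def params(self):
        return self.inner.params()

    def initialize(self, rng):
        self.inner.initialize(rng)

    def zero_init_tail(self) -> None:
        """Zero the last parameterized layer of the branch so the block
        starts as the identity (keeps activation variance from doubling
        per block in deep stacks)."""
        from .network import Sequential

        layers = self.inner.layers if isinstance(self.inner, Sequential) else [self.inner]
        for layer in reversed(layers):
            ps = layer.params()
            if ps:
                for p in ps:
                    p.value[...] = 0.0
                break

    def forward(self, x):
        return self.inner.forward(x) + x

    def backward(self, grad):
        return self.inner.backward(grad) + grad


class SqueezeExcite(Layer):
    """Channel gating: x * sigmoid(W2 relu(W1 gap(x)))."""

    def __init__(self, channels: int, reduction: int = 4) -> None:
        hidden = max(1, channels // reduction)
        self.c = channels
        self.fc1 = Dense(channels, hidden)
        self.fc2 = Dense(hidden, channels)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def initialize(self, rng):
        self.fc1.initialize(rng)
        self.fc2.initialize(rng)

    def forward(self, x):
        self._x = x
        self._spatial = x.shape[2:]
        z = x.mean(axis=tuple(range(2, x.ndim)))
        h = self.fc1.forward(z)
        self._h_mask = h > 0
        h = h * self._h_mask
        s = self.fc2.forward(h)
        self._gate = 1.0 / (1.0 + np.exp(-s))
        shape = (*self._gate.shape, *([1] * len(self._spatial)))
        return x * self._gate.reshape(shape)

    def backward(self, grad):
        x, gate = self._x, self._gate
        shape = (*gate.shape, *([1] * len(self._spatial)))
        gx = grad * gate.reshape(shape)
        g_gate = (grad * x).sum(axis=tuple(range(2, x.ndim)))
        gs = g_gate * gate * (1.0 - gate)
        gh = self.fc2.backward(gs) * self._h_mask
        gz = self.fc1.backward(gh)
        n = int(np.prod(self._spatial))
        shape_z = (*gz.shape, *([1] * len(self._spatial)))
        return gx + np.broadcast_to(gz.reshape(shape_z), x.shape) / n
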