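"""Sequential container, losses, and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param


class Sequential(Layer):
    """A chain of layers.

    ``forward`` caches every intermediate activation in ``outputs`` and
    ``backward`` caches the gradient flowing *into* every layer's output in
    ``output_grads`` — Grad-CAM reads both to form its activation/gradient
    pairs without any framework hooks.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)
        self.outputs: list[np.ndarray] = []
        self.output_grads: list[np.ndarray | None] = []

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def initialize(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.initialize(rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.outputs = []
        for layer in self.layers:
            x = layer.forward(x)
            self.outputs.append(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.output_grads = [None] * len(self.layers)
        for i in range(len(self.layers) - 1, -1, -1):
            self.output_grads[i] = grad
            grad = self.layers[i].backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of integer ``labels`` under softmax(logits).

    Returns (loss, grad_wrt_logits); the gradient is already divided by the
    batch size.
    """
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(np.maximum(p[np.arange(n), labels], eps)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
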