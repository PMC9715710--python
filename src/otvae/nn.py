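"""Minimal neural-network primitives on numpy with explicit backprop.

Layers are stateless with respect to activations: ``forward`` returns
``(output, cache)`` and ``backward(cache, grad_out)`` accumulates parameter
gradients in place and returns the gradient with respect to the input, so a
layer can be applied to several batches inside one step. All randomness goes
through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Linear:
    """Affine map with Kaiming-uniform weight init (for ReLU nets), zero bias."""

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "linear"):
        bound = np.sqrt(6.0 / fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)
        self.W = Parameter(W, f"{name}.W")
        self.b = Parameter(np.zeros(fan_out, dtype=dtype), f"{name}.b")

    def forward(self, x: np.ndarray):
        return x @ self.W.value + self.b.value, x

    def backward(self, cache, g: np.ndarray) -> np.ndarray:
        x = cache
        self.W.grad += x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    def parameters(self):
        return [self.W, self.b]


class BatchNorm:
    """1-d batch normalization with affine parameters and running statistics.

    Training mode normalizes by batch statistics (biased variance) and updates
    the running mean/variance with momentum (running variance uses the
    unbiased estimate); eval mode normalizes by the running statistics.
    """

    def __init__(self, dim: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn"):
        self.gamma = Parameter(np.ones(dim, dtype=dtype), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(dim, dtype=np.float64)
        self.running_var = np.ones(dim, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool):
        if training:
            n = x.shape[0]
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.astype(np.float64)
            unbiased = var * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased.astype(np.float64)
            out = self.gamma.value * xhat + self.beta.value
            return out, (xhat, inv_std.astype(x.dtype))
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = ((x - self.running_mean) * inv_std).astype(x.dtype)
        return self.gamma.value * xhat + self.beta.value, None

    def backward(self, cache, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = cache
        n = g.shape[0]
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gxhat = g * self.gamma.value
        return (inv_std / n) * (
            n * gxhat - gxhat.sum(axis=0) - xhat * (gxhat * xhat).sum(axis=0)
        )

    def parameters(self):
        return [self.gamma, self.beta]


def relu(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(mask: np.ndarray, g: np.ndarray) -> np.ndarray:
    return g * mask


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce(target: np.ndarray, prob: np.ndarray) -> np.ndarray:
    """Elementwise binary cross-entropy, clipped for finiteness of the value.

    The gradient with respect to pre-sigmoid logits is ``prob - target`` and
    is computed analytically where needed, so the clip affects only the
    reported loss value.
    """
    p = np.clip(prob, 1e-7, 1.0 - 1e-7)
    return -(target * np.log(p) + (1.0 - target) * np.log1p(-p))


class Adam:
    """Adam with decoupled-from-nothing torch-style L2 weight decay."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.value.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.value.dtype)
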