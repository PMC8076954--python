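"""Minimal feed-forward neural-network core in NumPy.

Provides exactly what the imputers need — dense layers, batch normalization,
ReLU, embedding tables, an MLP container, and the Adam update — with explicit
forward/backward passes. Everything is deterministic given a seeded
``numpy.random.Generator``; gradients are verified against finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Linear:
    """Affine map y = xW + b with He-scaled initialization (ReLU-friendly)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, *, scale=None):
        std = np.sqrt(2.0 / n_in) if scale is None else scale
        self.W = Param(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class BatchNorm:
    """Per-feature batch normalization with running statistics.

    Training uses batch statistics (population variance); inference uses the
    exponential running averages. A single-row training batch degrades to the
    running statistics to avoid a zero-variance normalization.
    """

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train and x.shape[0] > 1:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
            train = False
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, trained = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=0)
        self.beta.grad += gy.sum(axis=0)
        gxhat = gy * self.gamma.value
        if not trained:
            return gxhat * inv_std
        n = gy.shape[0]
        return (
            inv_std
            / n
            * (n * gxhat - gxhat.sum(axis=0) - xhat * (gxhat * xhat).sum(axis=0))
        )


class MLP:
    """Stack of Linear(+BatchNorm)+ReLU hidden blocks with a linear head."""

    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        n_out: int,
        rng: np.random.Generator,
        *,
        batch_norm: bool = True,
    ):
        self.layers: list = []
        d = n_in
        for h in hidden:
            self.layers.append(Linear(d, h, rng))
            if batch_norm:
                self.layers.append(BatchNorm(h))
            self.layers.append(ReLU())
            d = h
        # small-scale output init keeps early predictions near zero
        self.layers.append(Linear(d, n_out, rng, scale=np.sqrt(1.0 / d)))

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Embedding:
    """Lookup table of learnable vectors for a categorical covariate.

    Codes are 1-based (code k reads row k−1). Initialized uniformly in
    ±init_scale around zero.
    """

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator, init_scale=0.05):
        self.W = Param(rng.uniform(-init_scale, init_scale, size=(vocab_size, dim)))
        self._codes = None

    def params(self):
        return [self.W]

    def forward(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.int64)
        if codes.min(initial=1) < 1 or codes.max(initial=1) > self.W.value.shape[0]:
            raise ValueError(
                f"embedding code out of vocabulary 1..{self.W.value.shape[0]}"
            )
        self._codes = codes - 1
        return self.W.value[self._codes]

    def backward(self, gy: np.ndarray) -> None:
        np.add.at(self.W.grad, self._codes, gy)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def get_state(obj) -> list[np.ndarray]:
    """Snapshot of all parameter values and batch-norm running stats."""
    state = [p.value.copy() for p in obj.params()]
    for layer in getattr(obj, "layers", []):
        if isinstance(layer, BatchNorm):
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
    return state


def set_state(obj, state: list[np.ndarray]) -> None:
    it = iter(state)
    for p in obj.params():
        p.value[...] = next(it)
    for layer in getattr(obj, "layers", []):
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = next(it)
            layer.running_var[...] = next(it)
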