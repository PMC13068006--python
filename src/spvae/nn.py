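"""Neural-network building blocks and the Adam optimizer.

Layers operate on :class:`~spvae.autograd.Tensor` and keep their parameters
as tensors with ``requires_grad=True``.  Modules follow the usual
train/eval-mode convention: dropout is active and batch-norm uses minibatch
statistics only in training mode.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self) -> None:
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for module in self.modules():
            for value in module.__dict__.values():
                if isinstance(value, Tensor) and value.requires_grad:
                    params.append(value)
        return params

    def train(self) -> None:
        for module in self.modules():
            module.training = True

    def eval(self) -> None:
        for module in self.modules():
            module.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(
            rng.uniform(-scale, scale, size=(n_in, n_out)).astype(DTYPE), requires_grad=True
        )
        self.bias = (
            Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    """Batch normalization over feature columns with running statistics."""

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_features, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.n_updates = 0

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ag.batchnorm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(DTYPE)
            # unbiased running variance, as is conventional
            n = max(x.shape[0], 2)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var * n / (n - 1)
            ).astype(DTYPE)
            self.n_updates += 1
            return out
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class Adam:
    """Adam with additive (L2-style) weight decay."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 0.01,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
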