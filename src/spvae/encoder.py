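"""Per-group inference networks.

Each group has its own encoder (so gene sets may differ arbitrarily across
groups): counts are log1p-transformed, concatenated with the batch one-hot,
passed through two 128-unit ReLU layers and a dropout layer, and then
through four batch-normalized linear heads producing the means and
log-variances of the Gaussian posteriors over the private and shared latent
subspaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor

ArrayLike = Union[np.ndarray, Tensor]

LOGVAR_MIN, LOGVAR_MAX = -10.0, 10.0


@dataclass
class EncoderConfig:
    n_hidden: int = 128
    n_layers: int = 2
    dropout_rate: float = 0.1
    d_shared: int = 10
    d_private: int = 5

    def validate(self) -> None:
        if min(self.n_hidden, self.n_layers, self.d_shared, self.d_private) <= 0:
            raise ValueError("encoder dimensions must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class GaussianPosterior:
    """Diagonal-Gaussian posterior parameters, one row per cell."""

    mean: ArrayLike
    var: ArrayLike

    def numpy(self) -> "GaussianPosterior":
        m = self.mean.data if isinstance(self.mean, Tensor) else np.asarray(self.mean)
        v = self.var.data if isinstance(self.var, Tensor) else np.asarray(self.var)
        return GaussianPosterior(mean=m, var=v)

    def validate(self) -> None:
        p = self.numpy()
        if not (np.isfinite(p.mean).all() and np.isfinite(p.var).all()):
            raise ValueError("posterior parameters must be finite")
        if (p.var <= 0).any():
            raise ValueError("posterior variances must be strictly positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mean.shape


class _ParameterHead(nn.Module):
    """Batch-normalized input followed by a linear output layer.

    Normalization sits on the head's input rather than its output: a
    batch-norm after the output linear would hand the KL term a single
    scale parameter with which to shrink every posterior mean toward zero,
    which empirically collapses the posterior.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.bn = nn.BatchNorm1d(n_in)
        self.linear = nn.Linear(n_in, n_out, rng)

    def __call__(self, h: Tensor) -> Tensor:
        return self.linear(self.bn(h))


class GroupEncoder(nn.Module):
    """Inference network of one group."""

    def __init__(
        self,
        n_genes: int,
        n_batches: int,
        config: EncoderConfig,
        rng: np.random.Generator,
    ):
        super().__init__()
        config.validate()
        self.config = config
        self.n_genes = n_genes
        self.n_batches = n_batches
        n_in = n_genes + n_batches
        self.hidden = []
        self.hidden_bn = []
        for _ in range(config.n_layers):
            self.hidden.append(nn.Linear(n_in, config.n_hidden, rng))
            self.hidden_bn.append(nn.BatchNorm1d(config.n_hidden))
            n_in = config.n_hidden
        self.dropout = nn.Dropout(config.dropout_rate, rng)
        self.private_mean = _ParameterHead(config.n_hidden, config.d_private, rng)
        self.private_logvar = _ParameterHead(config.n_hidden, config.d_private, rng)
        self.shared_mean = _ParameterHead(config.n_hidden, config.d_shared, rng)
        self.shared_logvar = _ParameterHead(config.n_hidden, config.d_shared, rng)

    def __call__(
        self, x: np.ndarray, s_onehot: np.ndarray
    ) -> tuple[GaussianPosterior, GaussianPosterior]:
        if x.shape[1] != self.n_genes:
            raise ValueError(
                f"input has {x.shape[1]} genes, encoder expects {self.n_genes}"
            )
        h = Tensor(
            np.concatenate(
                [np.log1p(x).astype(nn.DTYPE), s_onehot.astype(nn.DTYPE)], axis=1
            )
        )
        for layer, bn in zip(self.hidden, self.hidden_bn):
            h = ag.relu(bn(layer(h)))
        h = self.dropout(h)

        def head(mean_head, logvar_head):
            mean = mean_head(h)
            logvar = ag.clamp(logvar_head(h), LOGVAR_MIN, LOGVAR_MAX)
            post = GaussianPosterior(mean=mean, var=ag.exp(logvar))
            if not np.isfinite(post.mean.data).all():
                raise FloatingPointError(
                    "non-finite encoder activations; training diverged"
                )
            return post

        private = head(self.private_mean, self.private_logvar)
        shared = head(self.shared_mean, self.shared_logvar)
        return private, shared


def encode_group(
    x: np.ndarray,
    s_onehot: np.ndarray,
    encoder: GroupEncoder,
) -> tuple[GaussianPosterior, GaussianPosterior]:
    """Functional wrapper around :class:`GroupEncoder`."""
    return encoder(x, s_onehot)


def reparameterize(
    posterior: GaussianPosterior, rng: np.random.Generator
) -> ArrayLike:
    """Draw z = mean + sqrt(var) * eps with eps ~ N(0, I).

    Gradients flow to the posterior parameters; the noise is a constant.
    """
    mean, var = posterior.mean, posterior.var
    shape = mean.shape
    eps = rng.standard_normal(shape).astype(
        mean.data.dtype if isinstance(mean, Tensor) else np.asarray(mean).dtype
    )
    if isinstance(mean, Tensor) or isinstance(var, Tensor):
        return mean + ag.sqrt(ag.as_tensor(var)) * Tensor(eps)
    return mean + np.sqrt(var) * eps
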