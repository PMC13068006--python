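"""Per-group generative networks: the negative-binomial mixture decoder.

Each gene's count is modeled as a negative binomial whose rate is a
mixture of two library-size-scaled "scale" vectors: a *private* scale rho
decoded linearly from the private latent sample, and a *shared* scale gamma
decoded linearly from the Product-of-Experts sample.  A small nonlinear
mixing network produces the per-cell, per-gene mixing probability pi that
arbitrates between the two decoder paths.  Both scale decoders are linear
(no hidden layers) so their weights are directly interpretable as gene
loadings; a learned batch-normalization follows each before the softmax.

Training marginalizes the Bernoulli path assignment exactly (see
``autograd.nb_two_part_mixture_loglik``); the mean-rate relaxation
(rate = pi*tau*gamma + (1-pi)*tau*rho) is kept here as the rate
interpretation of a fitted model, and count sampling draws the Bernoulli
explicitly.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy import special

from . import autograd as ag
from . import nn
from .autograd import Tensor

ArrayLike = Union[np.ndarray, Tensor]

THETA_FLOOR = 1e-4
RATE_EPS = 1e-8


class LinearScaleDecoder(nn.Module):
    """Affine map latent (+ batch covariates) -> gene logits -> BN -> softmax.

    The latent weight matrix is kept separate from the batch coefficients so
    factor loadings can be extracted without the covariate columns.
    """

    def __init__(self, d_latent: int, n_genes: int, n_batches: int, rng):
        super().__init__()
        self.latent = nn.Linear(d_latent, n_genes, rng, bias=False)
        self.batch = nn.Linear(n_batches, n_genes, rng, bias=False)
        self.bn = nn.BatchNorm1d(n_genes)
        # batch-norm standardizes the logits per gene, which amplifies
        # arbitrary structure to unit log-scale; starting the BN scale
        # small keeps the softmax near its offset profile until the latent
        # weights carry real signal
        self.bn.gamma.data[:] = 0.1

    def logits(self, z: ArrayLike, s: ArrayLike) -> Tensor:
        return self.bn(self.latent(ag.as_tensor(z)) + self.batch(ag.as_tensor(s)))

    def __call__(self, z: ArrayLike, s: ArrayLike) -> Tensor:
        return ag.softmax(self.logits(z, s), axis=1)


class MixingNetwork(nn.Module):
    """One 256-unit hidden layer; (z, s) re-injected before the output.

    The output bias starts positive (pi ~ 0.9) so reconstruction is routed
    through the shared path by default and the private path is recruited
    only where the shared representation cannot explain a gene's counts.
    Without this asymmetry the more expressive private path tends to seize
    the bulk of the likelihood early and the subspaces never specialize.
    """

    def __init__(
        self, d_in: int, n_genes: int, rng, n_hidden: int = 256, dropout: float = 0.1
    ):
        super().__init__()
        self.fc = nn.Linear(d_in, n_hidden, rng)
        self.bn = nn.BatchNorm1d(n_hidden)
        self.dropout = nn.Dropout(dropout, rng)
        self.out = nn.Linear(n_hidden + d_in, n_genes, rng)
        self.out.bias.data[:] = 4.0

    def __call__(self, zs: Tensor) -> Tensor:
        h = self.dropout(ag.relu(self.bn(self.fc(zs))))
        return ag.sigmoid(self.out(ag.concat([h, zs], axis=1)))


class GroupDecoder(nn.Module):
    """Generative networks and dispersions of one group."""

    def __init__(
        self,
        n_genes: int,
        d_private: int,
        d_shared: int,
        n_batches: int,
        rng: np.random.Generator,
        mixing_hidden: int = 256,
        dropout_rate: float = 0.1,
        scale_logit_init: np.ndarray | None = None,
        theta_init: np.ndarray | None = None,
    ):
        super().__init__()
        self.n_genes = n_genes
        self.d_private = d_private
        self.d_shared = d_shared
        self.n_batches = n_batches
        self.rho_decoder = LinearScaleDecoder(d_private, n_genes, n_batches, rng)
        self.gamma_decoder = LinearScaleDecoder(d_shared, n_genes, n_batches, rng)
        self.mixing = MixingNetwork(
            d_private + d_shared + n_batches, n_genes, rng, mixing_hidden, dropout_rate
        )
        if scale_logit_init is not None:
            # start both softmax scales at a given profile (e.g. empirical
            # mean gene proportions) so optimization spends its steps on
            # structure rather than on the per-gene mean offsets
            init = np.asarray(scale_logit_init, dtype=nn.DTYPE)
            init = init - init.mean()
            self.rho_decoder.bn.beta.data[:] = init
            self.gamma_decoder.bn.beta.data[:] = init
        # per-gene inverse dispersion, softplus-parameterized (theta > 0)
        if theta_init is None:
            raw = np.full(n_genes, 0.5413248, dtype=nn.DTYPE)  # softplus^-1(1)
        else:
            t = np.clip(np.asarray(theta_init, dtype=np.float64), 0.05, 1e4)
            raw = np.where(t > 30, t, np.log(np.expm1(np.minimum(t, 30.0)))).astype(
                nn.DTYPE
            )
        self.theta_raw = Tensor(raw, requires_grad=True)

    @property
    def theta(self) -> Tensor:
        return ag.softplus(self.theta_raw) + THETA_FLOOR

    def __call__(
        self, z_private: ArrayLike, z_poe: ArrayLike, s: ArrayLike
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Return (pi, rho, gamma), each cells x genes."""
        z_private = ag.as_tensor(z_private)
        z_poe = ag.as_tensor(z_poe)
        s = ag.as_tensor(s)
        rho = self.rho_decoder(z_private, s)
        gamma = self.gamma_decoder(z_poe, s)
        zs = ag.concat([z_private, z_poe, s], axis=1)
        pi = self.mixing(zs)
        if not np.isfinite(pi.data).all():
            raise FloatingPointError("non-finite decoder output")
        return pi, rho, gamma


def decode(
    z_private: ArrayLike, z_poe: ArrayLike, s: ArrayLike, params: GroupDecoder
) -> tuple[Tensor, Tensor, Tensor]:
    """Functional wrapper around :class:`GroupDecoder`."""
    return params(z_private, z_poe, s)


def nb_mixture_rate(
    pi: ArrayLike, tau: np.ndarray, rho: ArrayLike, gamma: ArrayLike
) -> ArrayLike:
    """Mixture rate pi*tau*gamma + (1-pi)*tau*rho (relaxed Bernoulli)."""
    tau_col = np.asarray(tau, dtype=np.float32).reshape(-1, 1)
    return pi * (tau_col * gamma) + (1.0 - pi) * (tau_col * rho)


def nb_log_likelihood(
    x: np.ndarray, rate: ArrayLike, theta: ArrayLike
) -> ArrayLike:
    """Per-cell log-likelihood of counts under NB(mean=rate, inverse dispersion=theta).

    Uses the log-gamma form of the NB pmf; summed over genes.
    """
    x = np.asarray(x)
    if (x < 0).any():
        raise ValueError("negative counts")
    x = x.astype(np.float32)
    tensor_mode = isinstance(rate, Tensor) or isinstance(theta, Tensor)
    rate = ag.as_tensor(rate)
    theta = ag.as_tensor(theta)
    log_theta_mu = ag.log(theta + rate + RATE_EPS)
    ll = (
        ag.lgamma(ag.as_tensor(x) + theta)
        - ag.lgamma(theta)
        - Tensor(special.gammaln(x + 1.0))
        + theta * (ag.log(theta + RATE_EPS) - log_theta_mu)
        + ag.as_tensor(x) * (ag.log(rate + RATE_EPS) - log_theta_mu)
    )
    total = ll.sum(axis=1)
    return total if tensor_mode else total.data


def sample_mixture_counts(
    pi: np.ndarray,
    tau: np.ndarray,
    rho: np.ndarray,
    gamma: np.ndarray,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generative sampling with an explicit Bernoulli path assignment."""
    w = rng.random(pi.shape) < pi
    tau_col = np.asarray(tau).reshape(-1, 1)
    rate = np.where(w, tau_col * gamma, tau_col * rho)
    shape = np.broadcast_to(theta, rate.shape)
    lam = rng.gamma(shape=shape, scale=rate / shape)
    return rng.poisson(lam)
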