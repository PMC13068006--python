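"""Entropic optimal-transport matching between two groups' shared posteriors.

When no labels are available, cell correspondences across groups are
inferred by solving an entropically regularized optimal-transport problem
between the two point clouds of shared-posterior means (uniform marginals,
Euclidean cost), via Sinkhorn iterations in the log domain.  The plan is
turned into either hard one-to-one partners (row argmax, the default) or
soft row-normalized weighted averages of the opposing group's posterior
parameters; either way the pair feeds the same Gaussian Product-of-Experts
used by the supervised model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import logsumexp

from . import autograd as ag
from .autograd import Tensor
from .encoder import GaussianPosterior
from .poe import combine_experts

ArrayLike = Union[np.ndarray, Tensor]


@dataclass
class TransportPlan:
    T: np.ndarray          # coupling, rows sum to 1/C1, columns to 1/C2
    epsilon: float
    converged: bool
    n_iters: int

    def validate(self, tol: float = 1e-6) -> None:
        c1, c2 = self.T.shape
        if (self.T < 0).any():
            raise ValueError("transport plan has negative entries")
        if np.abs(self.T.sum(axis=1) - 1.0 / c1).max() > tol:
            raise ValueError("row marginals violated")
        if np.abs(self.T.sum(axis=0) - 1.0 / c2).max() > tol:
            raise ValueError("column marginals violated")


def _euclidean_cost(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances via a single matrix product."""
    a = np.ascontiguousarray(z1, dtype=np.float32)
    b = np.ascontiguousarray(z2, dtype=np.float32)
    sq = (
        (a * a).sum(axis=1)[:, None]
        + (b * b).sum(axis=1)[None, :]
        - 2.0 * (a @ b.T)
    )
    return np.sqrt(np.maximum(sq, 0.0), dtype=np.float32).astype(np.float64)


def compute_transport_plan(
    z1: np.ndarray,
    z2: np.ndarray,
    epsilon: float = 1.0,
    max_iters: int = 1000,
    tol: float = 1e-9,
    normalize_cost: bool = False,
) -> TransportPlan:
    """Sinkhorn plan between two latent point clouds.

    Cost is the Euclidean distance between rows; marginals are uniform.
    Iterations run in the log domain and stop when the worst marginal
    violation falls below ``tol``.  With ``normalize_cost`` the cost matrix
    is divided by its median entry, which makes the regularization strength
    scale-free across latent geometries.
    """
    z1 = np.asarray(z1)
    z2 = np.asarray(z2)
    if z1.ndim != 2 or z2.ndim != 2 or z1.shape[1] != z2.shape[1]:
        raise ValueError("latent clouds must be 2-D with equal dimensionality")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not (np.isfinite(z1).all() and np.isfinite(z2).all()):
        raise ValueError("non-finite entries in the transport cost matrix")
    cost = _euclidean_cost(z1, z2)
    if normalize_cost:
        scale = np.median(cost)
        if scale > 0:
            cost = cost / scale
    c1, c2 = cost.shape
    log_a = np.full(c1, -np.log(c1))
    log_b = np.full(c2, -np.log(c2))
    log_K = -cost / epsilon
    f = np.zeros(c1)
    g = np.zeros(c2)
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        f = log_a - logsumexp(log_K + g[None, :], axis=1)
        g = log_b - logsumexp(log_K + f[:, None], axis=0)
        if it % 5 == 0 or it == max_iters:
            log_T = f[:, None] + log_K + g[None, :]
            row_err = np.abs(np.exp(logsumexp(log_T, axis=1)) - 1.0 / c1).max()
            if row_err < tol:
                converged = True
                break
    T = np.exp(f[:, None] + log_K + g[None, :])
    if not converged:
        warnings.warn(
            f"Sinkhorn did not reach tol={tol} in {max_iters} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return TransportPlan(T=T, epsilon=epsilon, converged=converged, n_iters=it)


def hard_match(plan: TransportPlan) -> np.ndarray:
    """Best partner in group 2 for each group-1 cell (row argmax of T).

    Ties resolve to the lowest column index (numpy argmax convention).
    """
    return np.argmax(plan.T, axis=1)


def soft_match_params(
    plan: TransportPlan, posterior2: GaussianPosterior
) -> GaussianPosterior:
    """Row-normalized-plan weighted average of group-2 posterior parameters."""
    row_sums = plan.T.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise ValueError("transport plan has a zero row; cannot normalize")
    T_bar = (plan.T / row_sums).astype(np.float32)
    mean, var = posterior2.mean, posterior2.var
    if isinstance(mean, Tensor) or isinstance(var, Tensor):
        T_t = Tensor(T_bar)
        return GaussianPosterior(
            mean=T_t @ ag.as_tensor(mean), var=T_t @ ag.as_tensor(var)
        )
    return GaussianPosterior(mean=T_bar @ mean, var=T_bar @ var)


def poe_from_matches(
    local: GaussianPosterior, matched: GaussianPosterior
) -> GaussianPosterior:
    """Per-cell Product of Experts of a local posterior and its match."""
    if local.shape != matched.shape:
        raise ValueError(
            f"shape mismatch between local {local.shape} and matched {matched.shape}"
        )
    mean, var = combine_experts(
        [(local.mean, local.var), (matched.mean, matched.var)]
    )
    return GaussianPosterior(mean=mean, var=var)
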