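"""Label-supervised Product-of-Experts over the shared latent space.

For every cell-type class, each group that observes the class contributes
one Gaussian "expert" (its class-level shared posterior); the joint shared
posterior is the normalized product of these experts with the standard-
normal prior.  For diagonal Gaussians the product is closed-form:
precisions add (the prior contributes precision 1) and the mean is the
precision-weighted average of expert means.

All functions accept either numpy arrays or autodiff tensors, so the same
code path serves training and post-hoc analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .encoder import GaussianPosterior

ArrayLike = Union[np.ndarray, Tensor]


def _asarray(x: ArrayLike) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


@dataclass
class ClassStats:
    """Per-class posterior parameters of one group (classes x d)."""

    classes: np.ndarray        # class codes present, ascending
    mean: ArrayLike
    var: ArrayLike


@dataclass
class ClassPoE:
    """Product-of-Experts parameters per class, plus expert bookkeeping."""

    classes: np.ndarray
    mean: ArrayLike
    var: ArrayLike
    contributing_groups: list[list[int]]


def class_aggregate(
    shared_posterior: GaussianPosterior,
    labels: np.ndarray,
    pooling: str = "product",
) -> ClassStats:
    """Pool per-cell posterior parameters into per-class parameters.

    ``product`` (default): the class posterior is the normalized product of
    the member cells' Gaussians - precisions add and means are precision-
    weighted, so the class posterior sharpens with the number of member
    cells.  This is the reading of a "posterior given the class subset"
    that treats every cell as an expert about its class.

    ``mean``: arithmetic mean of the members' means and variances; the
    class posterior keeps cell-level width regardless of class size.

    Classes absent from ``labels`` are omitted, not zero-filled.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != _asarray(shared_posterior.mean).shape[0]:
        raise ValueError("labels do not align with posterior rows")
    if pooling not in ("product", "mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    classes, inverse = np.unique(labels, return_inverse=True)
    pool = np.zeros((len(classes), len(labels)), dtype=np.float32)
    pool[inverse, np.arange(len(labels))] = 1.0
    if pooling == "mean":
        pool /= pool.sum(axis=1, keepdims=True)
    mean, var = shared_posterior.mean, shared_posterior.var
    tensor_mode = isinstance(mean, Tensor) or isinstance(var, Tensor)
    if tensor_mode:
        pool = Tensor(pool)
        mean = ag.as_tensor(mean)
        var = ag.as_tensor(var)
    if pooling == "mean":
        return ClassStats(classes, pool @ mean, pool @ var)
    precision = pool @ (1.0 / var)
    var_c = 1.0 / precision
    mean_c = var_c * (pool @ (mean / var))
    return ClassStats(classes, mean_c, var_c)


def combine_experts(
    experts: Sequence[tuple[ArrayLike, ArrayLike]]
) -> tuple[ArrayLike, ArrayLike]:
    """Product of Gaussian experts with the N(0, I) prior.

    precision = 1 + sum_i 1/var_i;  var = 1/precision;
    mean = var * sum_i mean_i/var_i.
    """
    if len(experts) == 0:
        raise ValueError("combine_experts needs at least one expert")
    precision = None
    weighted = None
    for mean, var in experts:
        p = 1.0 / var
        m = mean / var
        precision = p if precision is None else precision + p
        weighted = m if weighted is None else weighted + m
    precision = precision + 1.0
    var_poe = 1.0 / precision
    mean_poe = var_poe * weighted
    return mean_poe, var_poe


def combine_class_stats(stats: Sequence[ClassStats]) -> ClassPoE:
    """PoE across groups, class by class.

    Classes seen in only one group still get a PoE (single expert plus
    prior).  Implemented with scatter matrices so gradients flow through
    the class statistics of every contributing group.
    """
    if len(stats) == 0:
        raise ValueError("no class statistics provided")
    all_classes = np.unique(np.concatenate([s.classes for s in stats]))
    index = {c: i for i, c in enumerate(all_classes)}
    tensor_mode = any(isinstance(s.mean, Tensor) or isinstance(s.var, Tensor) for s in stats)
    precision = None
    weighted = None
    contributing: list[list[int]] = [[] for _ in all_classes]
    for g, s in enumerate(stats):
        scatter = np.zeros((len(all_classes), len(s.classes)), dtype=np.float32)
        for j, c in enumerate(s.classes):
            scatter[index[c], j] = 1.0
            contributing[index[c]].append(g)
        mean, var = s.mean, s.var
        if tensor_mode:
            scatter_t = Tensor(scatter)
            p = scatter_t @ (1.0 / ag.as_tensor(var))
            m = scatter_t @ (ag.as_tensor(mean) / ag.as_tensor(var))
        else:
            p = scatter @ (1.0 / var)
            m = scatter @ (mean / var)
        precision = p if precision is None else precision + p
        weighted = m if weighted is None else weighted + m
    precision = precision + 1.0
    var_poe = 1.0 / precision
    mean_poe = var_poe * weighted
    return ClassPoE(all_classes, mean_poe, var_poe, contributing)


def assemble_poe_tensor(class_poe: ClassPoE, labels: np.ndarray) -> GaussianPosterior:
    """Broadcast class-level PoE parameters back to cells.

    Row j of the result carries the PoE parameters of cell j's class.
    """
    labels = np.asarray(labels)
    index = {c: i for i, c in enumerate(class_poe.classes)}
    try:
        rows = np.array([index[l] for l in labels])
    except KeyError as err:
        raise KeyError(f"label {err.args[0]!r} has no PoE entry") from None
    mean, var = class_poe.mean, class_poe.var
    if isinstance(mean, Tensor) or isinstance(var, Tensor):
        return GaussianPosterior(
            mean=ag.take_rows(ag.as_tensor(mean), rows),
            var=ag.take_rows(ag.as_tensor(var), rows),
        )
    return GaussianPosterior(mean=np.asarray(mean)[rows], var=np.asarray(var)[rows])
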