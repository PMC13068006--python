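"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

The package trains its variational autoencoder with plain numpy linear
algebra; this module supplies the tape.  A :class:`Tensor` wraps an
``ndarray`` and records, for every differentiable operation, a closure that
propagates the upstream gradient to its parents.  ``backward()`` walks the
tape in reverse topological order.

Only the operations the model needs are implemented (affine maps,
elementwise transcendentals, reductions, concatenation, row gathering and
the log-gamma function used by the negative-binomial likelihood).  All
operations support numpy broadcasting; gradients are summed back over the
broadcast axes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # collapse leading extra dimensions
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from element-looping over Tensor operands; arithmetic with
    # ndarrays must go through the reflected operators below
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad or any(p.requires_grad for p in parents))
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.grad: np.ndarray | None = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient only allowed for scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g)
                if b.requires_grad:
                    b._accumulate(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g * b.data)
                if b.requires_grad:
                    b._accumulate(g * a.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g / b.data)
                if b.requires_grad:
                    b._accumulate(-g * a.data / (b.data * b.data))
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accumulate(
                g * exponent * a.data ** (exponent - 1)
            )
        return out

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad:
                    b._accumulate(a.data.T @ g)
            out._backward = backward
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def backward(g, a=self):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions ----------------------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.exp(x.data), parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, d=out.data: a._accumulate(g * d)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x: a._accumulate(g / a.data)
    return out


def log1p(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log1p(x.data), parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x: a._accumulate(g / (1.0 + a.data))
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.sqrt(x.data), parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, d=out.data: a._accumulate(g * 0.5 / d)
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    if out.requires_grad:
        mask = x.data > 0
        out._backward = lambda g, a=x, m=mask: a._accumulate(g * m)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = special.expit(x.data)
    out = Tensor(s, parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, d=s: a._accumulate(g * d * (1.0 - d))
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably."""
    x = as_tensor(x)
    out = Tensor(np.logaddexp(0.0, x.data), parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x: a._accumulate(g * special.expit(a.data))
    return out


def lgamma(x: Tensor) -> Tensor:
    """Log-gamma; gradient is the digamma function."""
    x = as_tensor(x)
    out = Tensor(special.gammaln(x.data), parents=(x,))
    if out.requires_grad:
        out._backward = lambda g, a=x: a._accumulate(g * special.psi(a.data))
    return out


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip to [lo, hi]; zero gradient outside the interval."""
    x = as_tensor(x)
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    if out.requires_grad:
        mask = (x.data >= lo) & (x.data <= hi)
        out._backward = lambda g, a=x, m=mask: a._accumulate(g * m)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` (max-shifted for stability); fused backward."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))
    if out.requires_grad:
        def backward(g, a=x, s=s):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))
        out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g, parts=tensors, sp=splits):
            pieces = np.split(g, sp, axis=axis)
            for t, piece in zip(parts, pieces):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = backward
    return out


def batchnorm_train(
    x: Tensor, gamma: Tensor, beta: Tensor, eps: float
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalization over axis 0.

    Returns the normalized tensor plus the batch mean and (biased) batch
    variance for running-statistics updates.
    """
    x = as_tensor(x)
    mu = x.data.mean(axis=0)
    centered = x.data - mu
    var = (centered * centered).mean(axis=0)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv_std
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    if out.requires_grad:
        def backward(g, a=x, gm=gamma, bt=beta, xhat=xhat, inv_std=inv_std):
            if bt.requires_grad:
                bt._accumulate(g.sum(axis=0))
            if gm.requires_grad:
                gm._accumulate((g * xhat).sum(axis=0))
            if a.requires_grad:
                n = xhat.shape[0]
                dxhat = g * gm.data
                a._accumulate(
                    inv_std
                    / n
                    * (
                        n * dxhat
                        - dxhat.sum(axis=0)
                        - xhat * (dxhat * xhat).sum(axis=0)
                    )
                )
        out._backward = backward
    return out, mu, var


def gaussian_kl(mean: Tensor, var: Tensor) -> Tensor:
    """Fused KL( N(mean, var) || N(0, I) ) summed over axis 1, per row."""
    mean = as_tensor(mean)
    var = as_tensor(var)
    kl = 0.5 * (mean.data**2 + var.data - 1.0 - np.log(var.data)).sum(axis=1)
    out = Tensor(kl, parents=(mean, var))
    if out.requires_grad:
        def backward(g, m=mean, v=var):
            gcol = g[:, None]
            if m.requires_grad:
                m._accumulate(gcol * m.data)
            if v.requires_grad:
                v._accumulate(gcol * 0.5 * (1.0 - 1.0 / v.data))
        out._backward = backward
    return out


def nb_mixture_loglik(
    x: np.ndarray,
    pi: Tensor,
    tau: np.ndarray,
    rho: Tensor,
    gamma: Tensor,
    theta: Tensor,
    eps: float = 1e-8,
) -> Tensor:
    """Fused negative-binomial mixture log-likelihood, summed over genes.

    rate = pi*tau*gamma + (1-pi)*tau*rho;  x ~ NB(mean=rate, inv disp=theta).
    Equivalent to composing ``nb_mixture_rate`` and ``nb_log_likelihood``
    from ``spvae.decoder``, but evaluated in one pass with an analytic
    backward, which is what makes minibatch training affordable.
    """
    pi, rho, gamma, theta = map(as_tensor, (pi, rho, gamma, theta))
    dt = np.result_type(pi.data.dtype, rho.data.dtype, np.float32)
    x = np.asarray(x, dtype=dt)
    tau_col = np.asarray(tau, dtype=dt).reshape(-1, 1)
    p = pi.data
    rate = p * (tau_col * gamma.data) + (1.0 - p) * (tau_col * rho.data)
    th = theta.data.astype(dt, copy=False)
    denom = th + rate + eps
    log_rate = np.log(rate + eps)
    log_denom = np.log(denom)
    ll = (
        special.gammaln(x + th)
        - special.gammaln(th)
        - special.gammaln(x + 1.0)
        + th * (np.log(th + eps) - log_denom)
        + x * (log_rate - log_denom)
    )
    out = Tensor(ll.sum(axis=1), parents=(pi, rho, gamma, theta))
    if out.requires_grad:
        def backward(g):
            gcol = g[:, None]
            dll_drate = x / (rate + eps) - (x + th) / denom
            drate = gcol * dll_drate
            if pi.requires_grad:
                pi._accumulate(
                    (drate * tau_col * (gamma.data - rho.data)).astype(pi.data.dtype)
                )
            if gamma.requires_grad:
                gamma._accumulate((drate * (p * tau_col)).astype(gamma.data.dtype))
            if rho.requires_grad:
                rho._accumulate(
                    (drate * ((1.0 - p) * tau_col)).astype(rho.data.dtype)
                )
            if theta.requires_grad:
                dll_dth = (
                    special.psi(x + th)
                    - special.psi(th)
                    + np.log(th + eps)
                    - log_denom
                    + 1.0
                    - (x + th) / denom
                )
                theta._accumulate(
                    (gcol * dll_dth).sum(axis=0).astype(theta.data.dtype)
                )
        out._backward = backward
    return out


def nb_two_part_mixture_loglik(
    x: np.ndarray,
    pi: Tensor,
    tau: np.ndarray,
    rho: Tensor,
    gamma: Tensor,
    theta: Tensor,
    eps: float = 1e-8,
) -> Tensor:
    """Marginalized Bernoulli-mixture NB log-likelihood, summed over genes.

    Each count is generated by the shared path with probability pi and the
    private path otherwise; marginalizing the path assignment gives

        log p(x) = logsumexp( log pi     + log NB(x; tau*gamma, theta),
                              log (1-pi) + log NB(x; tau*rho,   theta) ).

    Unlike the mean-rate relaxation this forbids blending the two paths
    into one intermediate rate, which is what forces the shared and
    private subspaces to specialize.  Gradients are the component
    responsibilities times the component NB gradients.
    """
    pi, rho, gamma, theta = map(as_tensor, (pi, rho, gamma, theta))
    dt = np.result_type(pi.data.dtype, rho.data.dtype, np.float32)
    x = np.asarray(x, dtype=dt)
    tau_col = np.asarray(tau, dtype=dt).reshape(-1, 1)
    p = np.clip(pi.data, 1e-6, 1.0 - 1e-6)
    th = theta.data.astype(dt, copy=False)
    log_th = np.log(th + eps)
    x_th = x + th
    lgam_const = special.gammaln(x_th) - special.gammaln(th) - special.gammaln(
        x + 1.0
    )

    rate_a = tau_col * gamma.data  # shared path
    rate_b = tau_col * rho.data    # private path
    denom_a = th + rate_a + eps
    denom_b = th + rate_b + eps
    log_denom_a = np.log(denom_a)
    log_denom_b = np.log(denom_b)
    la = np.log(p) + lgam_const + th * (log_th - log_denom_a) + x * (
        np.log(rate_a + eps) - log_denom_a
    )
    lb = np.log1p(-p) + lgam_const + th * (log_th - log_denom_b) + x * (
        np.log(rate_b + eps) - log_denom_b
    )
    m = np.maximum(la, lb)
    ll = m + np.log(np.exp(la - m) + np.exp(lb - m))
    out = Tensor(ll.sum(axis=1), parents=(pi, rho, gamma, theta))
    if out.requires_grad:
        def backward(g):
            gcol = g[:, None]
            ra = np.exp(la - ll)      # responsibility of the shared path
            rb = 1.0 - ra
            if pi.requires_grad:
                pi._accumulate(
                    (gcol * (ra / p - rb / (1.0 - p))).astype(pi.data.dtype)
                )
            if gamma.requires_grad:
                d_a = x / (rate_a + eps) - x_th / denom_a
                gamma._accumulate(
                    (gcol * ra * d_a * tau_col).astype(gamma.data.dtype)
                )
            if rho.requires_grad:
                d_b = x / (rate_b + eps) - x_th / denom_b
                rho._accumulate(
                    (gcol * rb * d_b * tau_col).astype(rho.data.dtype)
                )
            if theta.requires_grad:
                psi_const = special.psi(x_th) - special.psi(th) + log_th + 1.0
                grad_th = gcol * (
                    ra * (psi_const - log_denom_a - x_th / denom_a)
                    + rb * (psi_const - log_denom_b - x_th / denom_b)
                )
                theta._accumulate(grad_th.sum(axis=0).astype(theta.data.dtype))
        out._backward = backward
    return out


def take_rows(x: Tensor, indices: np.ndarray) -> Tensor:
    """Row gather ``x[indices]``; backward scatter-adds into the source rows."""
    x = as_tensor(x)
    idx = np.asarray(indices)
    out = Tensor(x.data[idx], parents=(x,))
    if out.requires_grad:
        def backward(g, a=x, i=idx):
            acc = np.zeros_like(a.data)
            np.add.at(acc, i, g)
            a._accumulate(acc)
        out._backward = backward
    return out
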