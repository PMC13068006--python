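"""Gradient correctness of the autodiff engine against numerical differentiation."""

import numpy as np
import pytest

from spvae import autograd as ag
from spvae.autograd import Tensor


def numerical_grad(fn, x, eps=1e-6):
    """Central-difference gradient of a scalar-valued fn at x (float64)."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        grad[idx] = (fn(xp) - fn(xm)) / (2 * eps)
        it.iternext()
    return grad


def analytic_grad(fn, x):
    t = Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
    out = fn(t)
    out.backward()
    return t.grad


@pytest.mark.parametrize(
    "name,fn,domain",
    [
        ("exp", lambda t: ag.exp(t).sum(), (-2, 2)),
        ("log", lambda t: ag.log(t).sum(), (0.1, 3)),
        ("log1p", lambda t: ag.log1p(t).sum(), (-0.5, 3)),
        ("sqrt", lambda t: ag.sqrt(t).sum(), (0.1, 4)),
        ("sigmoid", lambda t: ag.sigmoid(t).sum(), (-3, 3)),
        ("softplus", lambda t: ag.softplus(t).sum(), (-3, 3)),
        ("relu", lambda t: ag.relu(t).sum(), (0.1, 3)),
        ("lgamma", lambda t: ag.lgamma(t).sum(), (0.5, 5)),
        ("square", lambda t: (t * t).sum(), (-2, 2)),
        ("recip", lambda t: (1.0 / t).sum(), (0.5, 3)),
        ("pow", lambda t: (t**1.7).sum(), (0.5, 3)),
        ("softmax", lambda t: (ag.softmax(t, axis=1) * ag.softmax(t, axis=1)).sum(), (-2, 2)),
        ("mean_axis", lambda t: (t.mean(axis=0) ** 2.0).sum(), (-2, 2)),
    ],
)
def test_elementwise_gradients_match_numerical(name, fn, domain):
    rng = np.random.default_rng(7)
    x = rng.uniform(*domain, size=(3, 4))
    np.testing.assert_allclose(
        analytic_grad(fn, x), numerical_grad(lambda v: float(fn(Tensor(v)).data), x),
        rtol=1e-5, atol=1e-7,
    )


def test_matmul_and_broadcast_add_gradients():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(4, 3))
    B = rng.normal(size=(3, 5))
    b = rng.normal(size=5)

    def fn_a(a):
        return ((ag.as_tensor(a) @ Tensor(B) + Tensor(b)) ** 2.0).sum()

    np.testing.assert_allclose(
        analytic_grad(fn_a, A),
        numerical_grad(lambda v: float(fn_a(Tensor(v)).data), A),
        rtol=1e-6,
    )

    def fn_b(bias):
        return ((Tensor(A) @ Tensor(B) + ag.as_tensor(bias)) ** 2.0).sum()

    np.testing.assert_allclose(
        analytic_grad(fn_b, b),
        numerical_grad(lambda v: float(fn_b(Tensor(v)).data), b),
        rtol=1e-6,
    )


def test_take_rows_scatter_adds_duplicate_indices():
    x = Tensor(np.arange(6, dtype=float).reshape(3, 2), requires_grad=True)
    idx = np.array([0, 0, 2])
    out = ag.take_rows(x, idx).sum()
    out.backward()
    np.testing.assert_array_equal(x.grad, [[2.0, 2.0], [0.0, 0.0], [1.0, 1.0]])


def test_concat_splits_gradient():
    a = Tensor(np.ones((2, 2)), requires_grad=True)
    b = Tensor(np.ones((2, 3)), requires_grad=True)
    out = (ag.concat([a, b], axis=1) * np.arange(5.0)).sum()
    out.backward()
    np.testing.assert_array_equal(a.grad, [[0, 1], [0, 1]])
    np.testing.assert_array_equal(b.grad, [[2, 3, 4], [2, 3, 4]])


def test_ndarray_left_operand_defers_to_tensor():
    # numpy must not element-loop over Tensor operands
    x = np.ones((2, 2))
    t = Tensor(np.full((2, 2), 3.0), requires_grad=True)
    out = x * t + x
    assert isinstance(out, Tensor)
    assert out.data.shape == (2, 2)
    np.testing.assert_array_equal(out.data, 4.0 * x)


def test_batchnorm_train_gradients_match_numerical():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(6, 4))
    gamma = rng.uniform(0.5, 1.5, size=4)
    beta = rng.normal(size=4)

    def fn(v):
        out, _, _ = ag.batchnorm_train(
            ag.as_tensor(v), Tensor(gamma, requires_grad=True),
            Tensor(beta, requires_grad=True), 1e-5,
        )
        return (out**2.0).sum()

    np.testing.assert_allclose(
        analytic_grad(fn, x),
        numerical_grad(lambda v: float(fn(Tensor(v)).data), x),
        rtol=1e-4, atol=1e-6,
    )


def test_gaussian_kl_fused_matches_closed_form_and_gradient():
    rng = np.random.default_rng(5)
    mu = rng.normal(size=(4, 3))
    var = rng.uniform(0.3, 2.0, size=(4, 3))
    kl = ag.gaussian_kl(Tensor(mu), Tensor(var))
    expected = 0.5 * (mu**2 + var - 1 - np.log(var)).sum(axis=1)
    np.testing.assert_allclose(kl.data, expected, rtol=1e-6)

    def fn(v):
        return ag.gaussian_kl(Tensor(mu), ag.as_tensor(v)).sum()

    np.testing.assert_allclose(
        analytic_grad(fn, var),
        numerical_grad(lambda v: float(fn(Tensor(v)).data), var),
        rtol=1e-5,
    )


def test_marginal_mixture_matches_scipy_and_numerical_gradients():
    from scipy import stats

    rng = np.random.default_rng(13)
    C, G = 4, 6
    x = rng.poisson(5.0, size=(C, G)).astype(np.float64)
    pi = rng.uniform(0.2, 0.8, size=(C, G))
    rho = rng.dirichlet(np.ones(G), size=C)
    gamma = rng.dirichlet(np.ones(G), size=C)
    tau = rng.integers(50, 150, size=C).astype(np.float64)
    theta = rng.uniform(0.5, 3.0, size=G)

    ll = ag.nb_two_part_mixture_loglik(
        x, Tensor(pi), tau, Tensor(rho), Tensor(gamma), Tensor(theta)
    )
    # oracle: mixture of two scipy NB pmfs per entry
    mu_a = tau[:, None] * gamma
    mu_b = tau[:, None] * rho
    pmf = pi * stats.nbinom.pmf(x, theta, theta / (theta + mu_a)) + (
        1 - pi
    ) * stats.nbinom.pmf(x, theta, theta / (theta + mu_b))
    np.testing.assert_allclose(ll.data, np.log(pmf).sum(axis=1), rtol=1e-4)

    for name, build in [
        ("pi", lambda v: (ag.as_tensor(v), Tensor(rho), Tensor(gamma), Tensor(theta))),
        ("rho", lambda v: (Tensor(pi), ag.as_tensor(v), Tensor(gamma), Tensor(theta))),
        ("theta", lambda v: (Tensor(pi), Tensor(rho), Tensor(gamma), ag.as_tensor(v))),
    ]:
        base = {"pi": pi, "rho": rho, "theta": theta}[name]

        def fn(v):
            a, b, c, d = build(v)
            return ag.nb_two_part_mixture_loglik(x, a, tau, b, c, d).sum()

        np.testing.assert_allclose(
            analytic_grad(fn, base),
            numerical_grad(lambda v: float(fn(Tensor(v)).data), base, eps=1e-6),
            rtol=1e-3, atol=1e-5, err_msg=name,
        )


def test_fused_nb_mixture_matches_composed_ops():
    from spvae.decoder import nb_log_likelihood, nb_mixture_rate

    rng = np.random.default_rng(11)
    C, G = 5, 7
    x = rng.poisson(4.0, size=(C, G)).astype(np.float64)
    pi = rng.uniform(0.1, 0.9, size=(C, G))
    rho = rng.dirichlet(np.ones(G), size=C)
    gamma = rng.dirichlet(np.ones(G), size=C)
    tau = rng.integers(50, 150, size=C).astype(np.float64)
    theta = rng.uniform(0.5, 3.0, size=G)

    fused = ag.nb_mixture_loglik(
        x, Tensor(pi), tau, Tensor(rho), Tensor(gamma), Tensor(theta)
    )
    composed = nb_log_likelihood(x, nb_mixture_rate(pi, tau, rho, gamma), theta)
    np.testing.assert_allclose(fused.data, composed, rtol=1e-4)

    # gradient wrt theta against numerical differentiation of the fused op
    def fn(v):
        return ag.nb_mixture_loglik(
            x, Tensor(pi), tau, Tensor(rho), Tensor(gamma), ag.as_tensor(v)
        ).sum()

    np.testing.assert_allclose(
        analytic_grad(fn, theta),
        numerical_grad(lambda v: float(fn(Tensor(v)).data), theta, eps=1e-5),
        rtol=1e-3,
    )
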