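"""Sinkhorn transport plans against exact assignment oracles."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from spvae import (
    compute_transport_plan,
    hard_match,
    poe_from_matches,
    soft_match_params,
)
from spvae.encoder import GaussianPosterior
from spvae.transport import TransportPlan


class TestComputeTransportPlan:
    def test_marginals_are_uniform(self):
        rng = np.random.default_rng(0)
        plan = compute_transport_plan(
            rng.normal(size=(13, 3)), rng.normal(size=(9, 3)), epsilon=0.5
        )
        plan.validate(tol=1e-6)
        assert plan.converged

    def test_identical_separated_clouds_match_identity(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        plan = compute_transport_plan(pts, pts, epsilon=0.05)
        # mass concentrates on the matching index
        row_mass = plan.T / plan.T.sum(axis=1, keepdims=True)
        assert (np.diag(row_mass) >= 0.9).all()
        # and agrees with the exact LP assignment
        rows, cols = linear_sum_assignment(cdist(pts, pts))
        np.testing.assert_array_equal(hard_match(plan), cols)

    def test_2x2_symmetric_cost_small_epsilon_limit(self):
        # cost [[0,1],[1,0]]: optimal coupling puts all mass on the diagonal
        z1 = np.array([[0.0], [1.0]])
        z2 = np.array([[0.0], [1.0]])
        plan = compute_transport_plan(z1, z2, epsilon=0.01)
        np.testing.assert_allclose(plan.T, np.diag([0.5, 0.5]), atol=1e-3)

    def test_cost_approaches_assignment_cost_as_epsilon_shrinks(self):
        rng = np.random.default_rng(5)
        z1, z2 = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        cost = cdist(z1, z2)
        rows, cols = linear_sum_assignment(cost)
        exact = cost[rows, cols].sum() / 8  # uniform-marginal normalization
        gaps = []
        for eps in (1.0, 0.3, 0.05):
            plan = compute_transport_plan(z1, z2, epsilon=eps, max_iters=5000)
            gaps.append((plan.T * cost).sum() - exact)
        assert all(g >= -1e-6 for g in gaps)
        assert gaps[2] < gaps[0]
        assert gaps[2] < 0.05

    def test_non_finite_cost_rejected(self):
        z = np.array([[np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            compute_transport_plan(z, np.zeros((1, 2)), epsilon=1.0)

    def test_non_convergence_flagged_with_warning(self):
        rng = np.random.default_rng(1)
        with pytest.warns(RuntimeWarning, match="Sinkhorn"):
            plan = compute_transport_plan(
                rng.normal(size=(30, 2)), rng.normal(size=(40, 2)),
                epsilon=0.01, max_iters=3,
            )
        assert not plan.converged


class TestEpsilonSweep:
    def test_embedding_quality_reported_across_regularization_strengths(
        self, small_bundle
    ):
        """Training must tolerate any epsilon; probing quality is reported
        per value (stronger regularization should not crash or degenerate)."""
        import spvae
        from spvae import linear_probe, truth_tables

        bundle, truth = small_bundle
        tables = truth_tables(truth)
        cell_type = np.concatenate([t.cell_type.to_numpy() for t in tables])
        accuracies = {}
        for eps in (0.01, 0.1, 1.0):
            model, _ = spvae.train(
                bundle,
                spvae.EncoderConfig(d_shared=4, d_private=3),
                spvae.TrainingConfig(
                    mode="ot_hard", epochs=30, seed=0, ot_epsilon=eps, batch_size=64
                ),
            )
            latents = model.get_latents(bundle)
            acc = linear_probe(
                np.vstack(latents["poe"]), cell_type, seed=0
            ).mean_accuracy
            accuracies[eps] = acc
            assert 0.0 <= acc <= 1.0
        print(f"shared-space cell-type probing by epsilon: {accuracies}")


class TestHardMatch:
    def test_identity_plan(self):
        plan = TransportPlan(np.eye(4) / 4, 0.1, True, 1)
        np.testing.assert_array_equal(hard_match(plan), np.arange(4))

    def test_ties_break_to_lowest_index(self):
        T = np.array([[0.25, 0.25], [0.1, 0.4]])
        plan = TransportPlan(T, 0.1, True, 1)
        np.testing.assert_array_equal(hard_match(plan), [0, 1])

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(2)
        T = rng.random((10, 7))
        plan = TransportPlan(T, 0.1, True, 1)
        expected = [int(np.argmax(T[i])) for i in range(10)]
        np.testing.assert_array_equal(hard_match(plan), expected)


class TestSoftMatch:
    def test_one_hot_rows_reduce_to_hard_match(self):
        T = np.zeros((3, 3))
        T[0, 2] = T[1, 0] = T[2, 1] = 1 / 3
        plan = TransportPlan(T, 0.1, True, 1)
        post = GaussianPosterior(
            mean=np.arange(6.0).reshape(3, 2), var=np.ones((3, 2))
        )
        matched = soft_match_params(plan, post)
        np.testing.assert_allclose(matched.mean, post.mean[[2, 0, 1]])

    def test_uniform_rows_give_column_mean(self):
        plan = TransportPlan(np.full((2, 4), 1 / 8), 0.1, True, 1)
        mean = np.random.default_rng(0).normal(size=(4, 3))
        matched = soft_match_params(
            plan, GaussianPosterior(mean=mean, var=np.ones((4, 3)))
        )
        np.testing.assert_allclose(
            matched.mean, np.tile(mean.mean(axis=0), (2, 1)), rtol=1e-6
        )

    def test_matches_dense_matmul_oracle(self):
        rng = np.random.default_rng(3)
        T = rng.random((5, 6))
        plan = TransportPlan(T, 0.1, True, 1)
        mean = rng.normal(size=(6, 2))
        var = rng.uniform(0.5, 2.0, size=(6, 2))
        matched = soft_match_params(plan, GaussianPosterior(mean, var))
        T_bar = T / T.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(matched.mean, T_bar @ mean, rtol=1e-5)
        np.testing.assert_allclose(matched.var, T_bar @ var, rtol=1e-5)

    def test_zero_row_rejected(self):
        T = np.array([[0.0, 0.0], [0.5, 0.5]])
        plan = TransportPlan(T, 0.1, True, 1)
        with pytest.raises(ValueError, match="zero row"):
            soft_match_params(
                plan, GaussianPosterior(np.zeros((2, 1)), np.ones((2, 1)))
            )


class TestPoeFromMatches:
    def test_identical_partner_sharpens_posterior(self):
        post = GaussianPosterior(
            mean=np.full((4, 2), 1.5), var=np.full((4, 2), 0.8)
        )
        poe = poe_from_matches(post, post)
        assert (np.asarray(poe.var) < post.var).all()

    def test_closed_form_pair(self):
        local = GaussianPosterior(np.array([[2.0]]), np.array([[1.0]]))
        matched = GaussianPosterior(np.array([[0.0]]), np.array([[1.0]]))
        poe = poe_from_matches(local, matched)
        assert float(poe.mean[0, 0]) == pytest.approx(2.0 / 3.0)
        assert float(poe.var[0, 0]) == pytest.approx(1.0 / 3.0)

    def test_batched_equals_scalar_oracle(self):
        rng = np.random.default_rng(4)
        m1, v1 = rng.normal(size=(6, 3)), rng.uniform(0.2, 2, (6, 3))
        m2, v2 = rng.normal(size=(6, 3)), rng.uniform(0.2, 2, (6, 3))
        poe = poe_from_matches(GaussianPosterior(m1, v1), GaussianPosterior(m2, v2))
        for i in range(6):
            for j in range(3):
                prec = 1 + 1 / v1[i, j] + 1 / v2[i, j]
                assert float(poe.var[i, j]) == pytest.approx(1 / prec)
                assert float(poe.mean[i, j]) == pytest.approx(
                    (m1[i, j] / v1[i, j] + m2[i, j] / v2[i, j]) / prec
                )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            poe_from_matches(
                GaussianPosterior(np.zeros((2, 2)), np.ones((2, 2))),
                GaussianPosterior(np.zeros((3, 2)), np.ones((3, 2))),
            )
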