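"""Product-of-Experts correctness against an independent density oracle."""

import numpy as np
import pytest

from spvae import (
    assemble_poe_tensor,
    class_aggregate,
    combine_class_stats,
    combine_experts,
)
from spvae.encoder import GaussianPosterior
from spvae.poe import ClassStats


def product_oracle_1d(experts, grid=None):
    """Normalized product of expert densities with the N(0,1) prior,
    evaluated by direct multiplication on a dense grid."""
    if grid is None:
        grid = np.linspace(-12, 12, 200_001)
    log_density = -0.5 * grid**2  # standard-normal prior, unnormalized
    for mu, var in experts:
        log_density = log_density - 0.5 * (grid - mu) ** 2 / var
    density = np.exp(log_density - log_density.max())
    density /= np.trapezoid(density, grid)
    mean = np.trapezoid(grid * density, grid)
    var = np.trapezoid((grid - mean) ** 2 * density, grid)
    return mean, var


class TestCombineExperts:
    def test_single_unit_expert_tempered_by_prior(self):
        mu, var = combine_experts([(np.array(0.0), np.array(1.0))])
        assert mu == pytest.approx(0.0)
        assert var == pytest.approx(0.5)

    def test_two_unit_experts_closed_form(self):
        mu, var = combine_experts(
            [(np.array(2.0), np.array(1.0)), (np.array(0.0), np.array(1.0))]
        )
        assert var == pytest.approx(1.0 / 3.0)
        assert mu == pytest.approx(2.0 / 3.0)

    def test_symmetric_under_expert_swap(self):
        e1 = (np.array([1.0, -2.0]), np.array([0.5, 2.0]))
        e2 = (np.array([0.3, 0.7]), np.array([1.5, 0.25]))
        m12, v12 = combine_experts([e1, e2])
        m21, v21 = combine_experts([e2, e1])
        np.testing.assert_allclose(m12, m21)
        np.testing.assert_allclose(v12, v21)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_density_oracle(self, seed):
        rng = np.random.default_rng(seed)
        experts = [
            (rng.normal(scale=1.5), rng.uniform(0.3, 3.0))
            for _ in range(rng.integers(1, 4))
        ]
        mu, var = combine_experts(
            [(np.array(m), np.array(v)) for m, v in experts]
        )
        mu_oracle, var_oracle = product_oracle_1d(experts)
        assert abs(float(mu) - mu_oracle) < 1e-6
        assert abs(float(var) - var_oracle) < 1e-6

    def test_poe_variance_below_every_expert_and_prior(self):
        rng = np.random.default_rng(7)
        means = rng.normal(size=(3, 4))
        variances = rng.uniform(0.2, 5.0, size=(3, 4))
        _, v = combine_experts(list(zip(means, variances)))
        assert (v < variances).all()
        assert (v < 1.0).all()

    def test_empty_expert_list_rejected(self):
        with pytest.raises(ValueError):
            combine_experts([])


class TestClassAggregate:
    def test_singleton_class_is_identity(self):
        post = GaussianPosterior(
            mean=np.array([[1.0, 2.0], [5.0, 6.0]]),
            var=np.array([[0.5, 0.5], [2.0, 2.0]]),
        )
        stats = class_aggregate(post, np.array([0, 1]))
        np.testing.assert_array_equal(stats.classes, [0, 1])
        np.testing.assert_allclose(stats.mean, post.mean)
        np.testing.assert_allclose(stats.var, post.var)

    def test_two_cell_arithmetic_mean(self):
        post = GaussianPosterior(
            mean=np.array([[0.0], [2.0]]), var=np.array([[1.0], [3.0]])
        )
        stats = class_aggregate(post, np.array([7, 7]), pooling="mean")
        assert stats.mean[0, 0] == pytest.approx(1.0)
        assert stats.var[0, 0] == pytest.approx(2.0)

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(3)
        mean = rng.normal(size=(20, 3))
        var = rng.uniform(0.1, 2.0, size=(20, 3))
        labels = rng.integers(0, 4, size=20)
        stats = class_aggregate(GaussianPosterior(mean, var), labels, pooling="mean")
        for i, c in enumerate(stats.classes):
            np.testing.assert_allclose(stats.mean[i], mean[labels == c].mean(axis=0))
            np.testing.assert_allclose(stats.var[i], var[labels == c].mean(axis=0))

    def test_product_pooling_matches_gaussian_product_oracle(self):
        # default pooling: the class posterior is the normalized product of
        # its member-cell Gaussians (no prior factor at this stage)
        rng = np.random.default_rng(8)
        mean = rng.normal(size=(12, 2))
        var = rng.uniform(0.2, 2.5, size=(12, 2))
        labels = rng.integers(0, 3, size=12)
        stats = class_aggregate(GaussianPosterior(mean, var), labels)
        for i, c in enumerate(stats.classes):
            m, v = mean[labels == c], var[labels == c]
            prec = (1.0 / v).sum(axis=0)
            np.testing.assert_allclose(stats.var[i], 1.0 / prec, rtol=1e-5)
            np.testing.assert_allclose(
                stats.mean[i], (m / v).sum(axis=0) / prec, rtol=1e-5
            )

    def test_product_pooling_sharpens_with_class_size(self):
        post = GaussianPosterior(mean=np.zeros((8, 1)), var=np.ones((8, 1)))
        stats = class_aggregate(post, np.array([0] * 6 + [1] * 2))
        assert stats.var[0, 0] == pytest.approx(1 / 6)
        assert stats.var[1, 0] == pytest.approx(1 / 2)

    def test_absent_class_omitted(self):
        post = GaussianPosterior(mean=np.zeros((2, 1)), var=np.ones((2, 1)))
        stats = class_aggregate(post, np.array([3, 5]))
        assert list(stats.classes) == [3, 5]


class TestCombineClassStats:
    def test_class_present_in_one_group_gets_single_expert_poe(self):
        s1 = ClassStats(np.array([0]), np.array([[0.0]]), np.array([[1.0]]))
        s2 = ClassStats(np.array([1]), np.array([[4.0]]), np.array([[1.0]]))
        poe = combine_class_stats([s1, s2])
        np.testing.assert_array_equal(poe.classes, [0, 1])
        # class 0: expert (0,1) with prior -> var 1/2
        assert poe.var[0, 0] == pytest.approx(0.5)
        assert poe.mean[1, 0] == pytest.approx(2.0)  # 4/1 * 1/2
        assert poe.contributing_groups[0] == [0]
        assert poe.contributing_groups[1] == [1]

    def test_matches_pairwise_combine(self):
        rng = np.random.default_rng(0)
        m1, v1 = rng.normal(size=(2, 3)), rng.uniform(0.5, 2, (2, 3))
        m2, v2 = rng.normal(size=(2, 3)), rng.uniform(0.5, 2, (2, 3))
        poe = combine_class_stats(
            [
                ClassStats(np.array([0, 1]), m1, v1),
                ClassStats(np.array([0, 1]), m2, v2),
            ]
        )
        m_ref, v_ref = combine_experts([(m1, v1), (m2, v2)])
        np.testing.assert_allclose(poe.mean, m_ref, rtol=1e-6)
        np.testing.assert_allclose(poe.var, v_ref, rtol=1e-6)


class TestAssemblePoeTensor:
    def test_uniform_class_gives_identical_rows(self):
        poe = combine_class_stats(
            [ClassStats(np.array([0]), np.array([[1.0, 2.0]]), np.array([[1.0, 1.0]]))]
        )
        post = assemble_poe_tensor(poe, np.array([0, 0, 0]))
        assert post.mean.shape == (3, 2)
        assert (post.mean == post.mean[0]).all()

    def test_permuting_cells_permutes_rows(self):
        rng = np.random.default_rng(1)
        stats = ClassStats(
            np.array([0, 1, 2]), rng.normal(size=(3, 2)), rng.uniform(0.5, 2, (3, 2))
        )
        poe = combine_class_stats([stats])
        labels = np.array([0, 1, 2, 1])
        perm = np.array([3, 0, 2, 1])
        direct = assemble_poe_tensor(poe, labels[perm])
        permuted = assemble_poe_tensor(poe, labels)
        np.testing.assert_allclose(direct.mean, permuted.mean[perm])

    def test_rows_match_dictionary_lookup_oracle(self):
        rng = np.random.default_rng(2)
        classes = np.array([0, 1, 2])
        stats = ClassStats(
            classes, rng.normal(size=(3, 4)), rng.uniform(0.5, 2, (3, 4))
        )
        poe = combine_class_stats([stats])
        labels = rng.integers(0, 3, size=11)
        post = assemble_poe_tensor(poe, labels)
        lookup = {c: i for i, c in enumerate(poe.classes)}
        for j, l in enumerate(labels):
            np.testing.assert_allclose(post.mean[j], np.asarray(poe.mean)[lookup[l]])

    def test_missing_class_rejected(self):
        poe = combine_class_stats(
            [ClassStats(np.array([0]), np.zeros((1, 2)), np.ones((1, 2)))]
        )
        with pytest.raises(KeyError):
            assemble_poe_tensor(poe, np.array([0, 9]))
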