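"""Unit-level validation of the sum-of-trees sampler: prior formulas,
prediction arithmetic, marginal likelihoods against quadrature, and
conjugate full conditionals against closed forms."""

import numpy as np
import pytest
from scipy import integrate, stats

from aftbml import BartConfig, DecisionTree, Forest, nonterminal_prior_prob, predict
from aftbml.bart import (
    BartSampler,
    calibrate_tau,
    draw_tree_from_prior,
    gibbs_sigma2,
    leaf_marginal_loglik,
    tree_marginal_loglik,
)
from aftbml.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    InvalidStructureError,
)


class TestDepthPrior:
    @pytest.mark.parametrize("depth, alpha, gamma, expected", [
        (0, 0.95, 2.0, 0.95),
        (1, 0.95, 2.0, 0.2375),          # 0.95 * 2^-2
        (3, 0.95, 0.0, 0.95),            # gamma = 0 is depth-free
        (2, 0.5, 1.0, 0.5 / 3.0),
    ])
    def test_formula(self, depth, alpha, gamma, expected):
        assert nonterminal_prior_prob(depth, alpha, gamma) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [
        {"depth": -1, "alpha": 0.95, "gamma": 2.0},
        {"depth": 0, "alpha": 1.0, "gamma": 2.0},
        {"depth": 0, "alpha": 0.0, "gamma": 2.0},
        {"depth": 0, "alpha": 0.95, "gamma": -0.1},
    ])
    def test_domain_violations(self, bad):
        with pytest.raises(InvalidParameterError):
            nonterminal_prior_prob(**bad)

    def test_prior_sampled_trees_match_formula(self, rng):
        """Empirical nonterminal frequencies of prior-sampled trees agree
        with alpha (1 + depth)^-gamma at the root and at depth 1."""
        cfg = BartConfig(n_trees=1, alpha=0.95, gamma=2.0, tau=1.0)
        X = rng.uniform(size=(60, 3))
        n_trees = 4000
        root_internal = 0
        d1_nodes = 0
        d1_internal = 0
        for _ in range(n_trees):
            tree = draw_tree_from_prior(X, cfg, rng)
            if tree.ntype[0] == 1:
                root_internal += 1
                for k in (1, 2):
                    d1_nodes += 1
                    d1_internal += tree.ntype[k] == 1
        p_root = root_internal / n_trees
        se = np.sqrt(0.95 * 0.05 / n_trees)
        assert abs(p_root - 0.95) < 4 * se
        p1 = d1_internal / d1_nodes
        se1 = np.sqrt(0.2375 * (1 - 0.2375) / d1_nodes)
        assert abs(p1 - 0.2375) < 4 * se1

    def test_prior_marginal_f_variance_is_tau_squared(self, rng):
        """f(x) is a sum of r independent N(0, tau^2/r) leaves, so its
        prior variance at any x is tau^2."""
        tau = 0.8
        cfg = BartConfig(n_trees=20, tau=tau)
        X = rng.uniform(size=(40, 2))
        x0 = X[:3]
        preds = []
        for _ in range(600):
            forest = Forest([draw_tree_from_prior(X, cfg, rng)
                             for _ in range(cfg.n_trees)], n_features=2)
            preds.append(forest.predict(x0))
        v = np.var(np.array(preds), axis=0)
        assert np.all(np.abs(v - tau ** 2) < 0.15 * tau ** 2)


class TestPrediction:
    def test_empty_forest_predicts_zero(self):
        assert predict(Forest([]), np.array([1.0, 2.0])) == 0.0

    def test_single_leaf_constant(self):
        forest = Forest([DecisionTree.stub(1.7)])
        assert predict(forest, np.array([0.3])) == pytest.approx(1.7)

    def test_two_stubs_add(self):
        forest = Forest([DecisionTree.stub(0.4), DecisionTree.stub(-0.1)])
        assert predict(forest, np.array([9.9])) == pytest.approx(0.3)

    def test_forest_prediction_is_sum_of_trees(self, rng):
        cfg = BartConfig(n_trees=1, tau=1.0)
        X = rng.uniform(size=(50, 4))
        trees = [draw_tree_from_prior(X, cfg, rng) for _ in range(8)]
        forest = Forest(trees, n_features=4)
        total = sum(t.predict(X) for t in trees)
        np.testing.assert_allclose(forest.predict(X), total, atol=1e-12)

    def test_split_routes_ties_left(self):
        tree = DecisionTree.from_split(0, 0.5, -1.0, 1.0)
        out = tree.predict(np.array([[0.5], [0.500001]]))
        assert out[0] == -1.0 and out[1] == 1.0

    def test_dimension_mismatch_rejected(self):
        forest = Forest([DecisionTree.stub(0.0)], n_features=3)
        with pytest.raises(InvalidInputError):
            forest.predict(np.zeros((2, 2)))


class TestMarginalLikelihood:
    def test_single_leaf_matches_quadrature(self):
        resid = np.array([0.0, 0.0])
        sigma2, tau2r = 0.7, 0.25

        def integrand(m):
            return (stats.norm.pdf(0.0, m, np.sqrt(sigma2)) ** 2
                    * stats.norm.pdf(m, 0.0, np.sqrt(tau2r)))

        expected, _ = integrate.quad(integrand, -10, 10)
        got = leaf_marginal_loglik(resid, sigma2, tau2r)
        assert got == pytest.approx(np.log(expected), rel=1e-8)

    def test_quadrature_general_residuals(self, rng):
        resid = rng.normal(size=5)
        sigma2, tau2r = 0.4, 0.9

        def integrand(m):
            return (np.prod(stats.norm.pdf(resid, m, np.sqrt(sigma2)))
                    * stats.norm.pdf(m, 0.0, np.sqrt(tau2r)))

        expected, _ = integrate.quad(integrand, -15, 15)
        got = leaf_marginal_loglik(resid, sigma2, tau2r)
        assert got == pytest.approx(np.log(expected), rel=1e-7)

    def test_tree_marginal_sums_over_leaves(self, rng):
        """A two-leaf tree's marginal equals the sum of per-leaf marginals
        of the induced residual partition."""
        X = np.linspace(0, 1, 10)[:, None]
        resid = rng.normal(size=10)
        tree = DecisionTree.from_split(0, 0.45, 0.0, 0.0)
        left = resid[X[:, 0] <= 0.45]
        right = resid[X[:, 0] > 0.45]
        expected = (leaf_marginal_loglik(left, 0.5, 0.2)
                    + leaf_marginal_loglik(right, 0.5, 0.2))
        got = tree_marginal_loglik(tree, X, resid, 0.5, 0.2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_vanishing_leaf_prior_gives_plain_normal(self, rng):
        resid = rng.normal(size=6)
        sigma2 = 0.5
        got = leaf_marginal_loglik(resid, sigma2, 1e-12)
        expected = stats.norm.logpdf(resid, 0.0, np.sqrt(sigma2)).sum()
        assert got == pytest.approx(expected, abs=1e-6)

    def test_empty_leaf_signals_invalid_structure(self):
        X = np.array([[0.1], [0.2]])
        tree = DecisionTree.from_split(0, 0.9, 0.0, 0.0)  # right leaf empty
        with pytest.raises(InvalidStructureError):
            tree_marginal_loglik(tree, X, np.zeros(2), 1.0, 0.1)


class TestConjugateFullConditionals:
    def test_single_leaf_sampler_matches_normal_means_posterior(self, rng):
        """With one tree and structural moves disabled, the leaf draw is an
        exact conjugate normal-means posterior sample."""
        n = 25
        y = rng.normal(1.5, 1.0, n)
        sigma2, tau2r = 0.8, 0.6
        cfg = BartConfig(n_trees=1, tau=np.sqrt(tau2r), n_burn=0, n_draws=1,
                         move_probabilities=(0.0, 0.0, 1.0), seed=3)
        sampler = BartSampler(np.zeros((n, 1)), y, cfg, sigma2=sigma2)
        draws = []
        for _ in range(4000):
            sampler.sweep(update_sigma=False)
            draws.append(sampler.leaf[0, 0])
        draws = np.array(draws)
        post_var = 1.0 / (1.0 / tau2r + n / sigma2)
        post_mean = post_var * y.sum() / sigma2
        assert abs(draws.mean() - post_mean) < 4 * np.sqrt(post_var / draws.size)
        assert np.var(draws) == pytest.approx(post_var, rel=0.15)

    def test_sigma2_full_conditional_moment(self, rng):
        """With zero residuals the sigma^2 draw is nu*lambda/chi2(nu+n),
        whose mean is nu*lambda/(nu+n-2)."""
        nu, lam, n = 3.0, 0.7, 40
        draws = np.array([gibbs_sigma2(0.0, n, nu, lam, rng) for _ in range(40000)])
        expected = nu * lam / (nu + n - 2)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 4 * se

    def test_structural_moves_change_internal_count_by_at_most_one(self, rng):
        y = None
        x = rng.uniform(size=(80, 2))
        y = np.where(x[:, 0] > 0.5, 1.0, -1.0) + rng.normal(0, 0.2, 80)
        cfg = BartConfig(n_trees=1, n_burn=0, n_draws=1, tau=0.5,
                        move_probabilities=(0.45, 0.45, 0.1), seed=11)
        sampler = BartSampler(x, y, cfg, sigma2=0.04)
        counts = [sampler.forest.trees[0].n_internal]
        for _ in range(200):
            sampler.sweep(update_sigma=False)
            counts.append(sampler.forest.trees[0].n_internal)
        diffs = np.diff(counts)
        assert np.all(np.abs(diffs) <= 1)
        assert max(counts) >= 1  # informative data: some grow is accepted

    def test_grow_then_matching_prune_restores_structure(self, rng):
        """Bookkeeping smoke test of reversibility: growing a leaf and
        pruning the same node returns the identical tree arrays."""
        from aftbml._compiled import INTERNAL, LEAF, UNUSED
        tree = DecisionTree.stub(0.3)
        before = (tree.ntype.copy(), tree.var.copy(), tree.cut.copy())
        # grow root on feature 0 at 0.5
        tree.ntype[0] = INTERNAL
        tree.var[0] = 0
        tree.cut[0] = 0.5
        tree.ntype[1] = tree.ntype[2] = LEAF
        # matching prune
        tree.ntype[1] = tree.ntype[2] = UNUSED
        tree.ntype[0] = LEAF
        tree.var[0] = -1
        tree.cut[0] = 0.0
        after = (tree.ntype, tree.var, tree.cut)
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_trees": 0}, {"alpha": 1.2}, {"gamma": -1.0}, {"nu": 0.0},
        {"q": 1.0}, {"n_draws": 0}, {"move_probabilities": (0.5, 0.5, 0.5)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            BartConfig(**kwargs)

    def test_tau_calibration_spans_range(self):
        y = np.array([-2.0, 6.0])
        assert calibrate_tau(y, k=2.0) == pytest.approx(2.0)
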