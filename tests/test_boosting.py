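"""GOSS sampling, variance gain against exact oracles, and tree-constraint
audits of fitted boosting models."""

import numpy as np
import pytest

import lungct as lc
from lungct.boosting import (GBDTParams, fit_gbdt, goss_sample, normalize01,
                             predict_proba, variance_gain)


class TestNormalize:
    def test_hand_values(self):
        assert np.allclose(normalize01([2, 4, 6]), [0.0, 0.5, 1.0])

    def test_endpoints_and_order_preserved(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        z = normalize01(y)
        assert z.min() == 0.0 and z.max() == 1.0
        assert np.array_equal(np.argsort(y), np.argsort(z))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize01([3.0, 3.0])


class TestGossSample:
    def test_b_equal_one_keeps_everything_at_weight_one(self):
        g = np.random.default_rng(0).normal(size=40)
        idx, w = goss_sample(g, b=1.0, c=0.5, seed=1)
        assert np.array_equal(idx, np.arange(40))
        assert np.all(w == 1.0)

    def test_counts_and_amplification_factor(self):
        g = np.random.default_rng(1).normal(size=1000)
        idx, w = goss_sample(g, b=0.2, c=0.1, seed=2)
        assert len(idx) == 300
        assert (w == 1.0).sum() == 200
        assert np.sum(np.isclose(w, (1 - 0.2) / 0.1)) == 100

    def test_top_set_is_exactly_largest_gradients(self):
        g = np.random.default_rng(2).normal(size=500)
        idx, w = goss_sample(g, b=0.2, c=0.1, seed=3)
        kept_top = set(idx[w == 1.0])
        true_top = set(np.argsort(-np.abs(g))[:100])
        assert kept_top == true_top

    def test_amplified_sums_unbiased_within_three_se(self):
        # E[sum of amplified sampled gradients] = full gradient sum
        rng = np.random.default_rng(3)
        g = rng.normal(size=200)
        full = g.sum()
        draws = np.empty(2000)
        for k in range(2000):
            idx, w = goss_sample(g, b=0.2, c=0.1, seed=k)
            draws[k] = (w * g[idx]).sum()
        se = draws.std(ddof=1) / np.sqrt(2000)
        assert abs(draws.mean() - full) < 3 * se


class TestVarianceGain:
    @pytest.mark.parametrize("seed", range(3))
    def test_b_one_matches_exact_two_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 8))
        g = rng.normal(size=50)
        w = np.ones(50)
        for k in range(8):
            for e in np.unique(X[:, k])[:-1]:
                left = X[:, k] <= e
                o_l, o_r = left.sum(), 50 - left.sum()
                oracle = (sum(g[left]) ** 2 / o_l
                          + sum(g[~left]) ** 2 / o_r) / 50
                assert variance_gain(X[:, k], g, w, e) == pytest.approx(
                    oracle, abs=1e-12)

    def test_perfect_split_dominates(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        g = np.concatenate([np.ones(20), -np.ones(20)])
        w = np.ones(40)
        best = variance_gain(x, g, w, 0.5)
        rng = np.random.default_rng(0)
        x2 = rng.random(40)  # non-separating feature
        for e in np.sort(x2)[5:-5:4]:
            assert best > variance_gain(x2, g, w, e)

    def test_quadratic_in_gradient_scale(self):
        rng = np.random.default_rng(1)
        x, g = rng.random(30), rng.normal(size=30)
        w = np.ones(30)
        e = np.median(x)
        assert variance_gain(x, 3 * g, w, e) == pytest.approx(
            9 * variance_gain(x, g, w, e))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            variance_gain(np.arange(5.0), np.ones(5), np.ones(5), 10.0)


def separable_data(n=500, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    return X, y


def audit_tree(tree, p: GBDTParams):
    leaves = 0
    for i in range(len(tree["feature"])):
        if tree["feature"][i] < 0:
            leaves += 1
            assert tree["count"][i] >= p.min_data_in_leaf
            assert tree["depth"][i] <= p.max_depth
    assert leaves <= p.num_leaves
    return leaves


class TestFitGBDT:
    def test_separable_training_accuracy(self):
        X, y = separable_data()
        p = GBDTParams(n_iterations=50, seed=0)
        model = fit_gbdt(X, y, p)
        acc = np.mean((predict_proba(model, X) >= 0.5) == y)
        assert acc >= 0.99

    def test_leaf_depth_and_mdl_constraints_hold(self):
        X, y = separable_data(n=400, seed=1)
        p = GBDTParams(min_data_in_leaf=40, num_leaves=8, max_depth=3,
                       n_iterations=20, seed=1)
        model = fit_gbdt(X, y, p)
        assert len(model.trees) == 20
        for tree in model.trees:
            audit_tree(tree, p)

    def test_loss_nonincreasing_without_sampling(self):
        X, y = separable_data(n=300, seed=2)
        losses = []
        for nti in (1, 5, 10, 20, 40):
            m = fit_gbdt(X, y, GBDTParams(n_iterations=nti, goss_b=1.0,
                                          goss_c=1.0, seed=2))
            prob = np.clip(predict_proba(m, X), 1e-12, 1 - 1e-12)
            losses.append(-np.mean(y * np.log(prob)
                                   + (1 - y) * np.log(1 - prob)))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_goss_training_still_reduces_loss(self):
        X, y = separable_data(n=500, seed=3)
        m0 = fit_gbdt(X, y, GBDTParams(n_iterations=1, seed=3))
        m1 = fit_gbdt(X, y, GBDTParams(n_iterations=50, seed=3))

        def loss(m):
            prob = np.clip(predict_proba(m, X), 1e-12, 1 - 1e-12)
            return -np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob))

        assert loss(m1) < loss(m0)

    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(100, 2))
        with pytest.raises(ValueError):
            fit_gbdt(X, np.zeros(100))

    def test_sklearn_estimator_interface(self):
        X, y = separable_data(n=200, seed=4)
        clf = lc.GOSSBoostingClassifier(n_iterations=20, random_state=0)
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (200, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert clf.get_params()["n_iterations"] == 20

    def test_comparable_to_lightgbm_reference(self):
        lgb = pytest.importorskip("lightgbm")
        X, y = separable_data(n=400, seed=5)
        ours = lc.GOSSBoostingClassifier(n_iterations=50,
                                         random_state=0).fit(X, y)
        ref = lgb.LGBMClassifier(n_estimators=50, data_sample_strategy="goss",
                                 verbose=-1, random_state=0).fit(X, y)
        acc_ours = ours.score(X, y)
        acc_ref = float(np.mean(ref.predict(X) == y))
        assert acc_ours >= acc_ref - 0.02
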