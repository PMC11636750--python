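"""Spiral search primitives, rough-set dependency, and reduct recovery."""

import numpy as np
import pytest

import lungct as lc
from lungct.selection import (DecisionTable, SpiralConfig, discretize_table,
                              exhaustive_reduct, gamma_dependency,
                              rotation_matrix, select_features, spiral_step,
                              step_rate)


class TestRotationMatrix:
    def test_two_dimensional_block_form(self):
        assert np.array_equal(rotation_matrix(2),
                              np.array([[0.0, -1.0], [1.0, 0.0]]))

    @pytest.mark.parametrize("n", range(2, 11))
    def test_orthogonality(self, n):
        R = rotation_matrix(n)
        assert np.allclose(R @ R.T, np.eye(n), atol=1e-12)

    def test_fourth_power_is_identity_in_2d(self):
        R = rotation_matrix(2)
        assert np.allclose(np.linalg.matrix_power(R, 4), np.eye(2))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rotation_matrix(1)


class TestStepRate:
    def test_periodic_descent_constant_value(self):
        cfg = SpiralConfig(delta=1e-3, k_max=100, mode="periodic_descent")
        r = step_rate(0, cfg, 12)
        assert r == pytest.approx(0.001 ** 0.01)
        assert r == pytest.approx(0.93325, abs=1e-5)
        assert step_rate(57, cfg, 12) == r

    def test_convergence_schedule_cases(self):
        cfg = SpiralConfig(delta=0.5, mode="convergence", k_star=3)
        n = 7
        assert step_rate(3, cfg, n) == 1.0
        assert step_rate(3 + 2 * n - 1, cfg, n) == 1.0
        assert step_rate(3 + 2 * n, cfg, n) == pytest.approx(0.5 ** (1 / 14))

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            SpiralConfig(delta=0.0)


class TestSpiralStep:
    def test_center_point_is_fixed(self):
        R = rotation_matrix(3)
        c = np.array([0.5, 0.5, 0.5])
        out = spiral_step(c[None, :], c, 0.9, R)
        assert np.allclose(out[0], c)

    @pytest.mark.parametrize("r", [1.0, 0.5])
    def test_distances_scale_by_rate(self, r):
        R = rotation_matrix(4)
        rng = np.random.default_rng(0)
        pts = rng.random((6, 4))
        c = rng.random(4)
        out = spiral_step(pts, c, r, R)
        d0 = np.linalg.norm(pts - c, axis=1)
        d1 = np.linalg.norm(out - c, axis=1)
        assert np.allclose(d1, r * d0, atol=1e-12)


def toy_table():
    # attr 0 separates the decision classes; attr 1 is pure noise
    return DecisionTable(X=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
                         d=np.array([0, 0, 1, 1]))


class TestGammaDependency:
    def test_consistent_table_full_set_is_one(self):
        assert gamma_dependency(toy_table(), np.array([0, 1])) == 1.0

    def test_empty_subset_with_mixed_decisions_is_zero(self):
        assert gamma_dependency(toy_table(), np.array([], dtype=int)) == 0.0

    def test_informative_singleton_oracle(self):
        # brute force: partition by attr 0 -> classes {0,1},{2,3} both pure
        assert gamma_dependency(toy_table(), np.array([0])) == 1.0
        assert gamma_dependency(toy_table(), np.array([1])) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_under_attribute_addition(self, seed):
        rng = np.random.default_rng(seed)
        t = DecisionTable(X=rng.integers(0, 3, (30, 5)),
                          d=rng.integers(0, 2, 30))
        for _ in range(10):
            cols = rng.permutation(5)
            k = rng.integers(0, 5)
            small = cols[:k]
            big = cols[:k + 1]
            assert (gamma_dependency(t, small)
                    <= gamma_dependency(t, big) + 1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        t = DecisionTable(X=rng.integers(0, 2, (40, 4)),
                          d=rng.integers(0, 2, 40))
        for k in range(5):
            g = gamma_dependency(t, np.arange(k))
            assert 0.0 <= g <= 1.0


def planted_table(seed=42, n_obj=60, n_noise=10):
    rng = np.random.default_rng(seed)
    f1 = rng.integers(0, 4, n_obj)
    f2 = rng.integers(0, 4, n_obj)
    d = ((f1 + f2) % 2).astype(int)
    X = np.column_stack([f1, f2, rng.integers(0, 4, (n_obj, n_noise))])
    return DecisionTable(X=X, d=d)


class TestExhaustiveReduct:
    def test_single_informative_attribute(self):
        mask = exhaustive_reduct(toy_table())
        assert np.array_equal(mask, [True, False])

    def test_duplicated_columns_excluded(self):
        t = toy_table()
        dup = DecisionTable(X=np.column_stack([t.X, t.X[:, 0]]), d=t.d)
        mask = exhaustive_reduct(dup)
        assert mask.sum() == 1

    def test_reduct_preserves_gamma(self):
        t = planted_table()
        mask = exhaustive_reduct(t)
        assert gamma_dependency(t, mask) == gamma_dependency(
            t, np.arange(t.n_attributes))

    def test_large_n_refused(self):
        t = DecisionTable(X=np.zeros((4, 15), dtype=int),
                          d=np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            exhaustive_reduct(t)


class TestSelectFeatures:
    def test_fixed_seed_is_deterministic(self):
        t = planted_table()
        a = select_features(t, SpiralConfig(seed=3))
        b = select_features(t, SpiralConfig(seed=3))
        assert np.array_equal(a, b)

    def test_selection_preserves_full_set_gamma(self):
        rng = np.random.default_rng(0)
        t = DecisionTable(X=rng.integers(0, 3, (50, 8)),
                          d=rng.integers(0, 2, 50))
        mask = select_features(t, SpiralConfig(seed=1, k_max=30))
        assert gamma_dependency(t, mask) == pytest.approx(
            gamma_dependency(t, np.arange(8)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_planted_minimal_reduct(self, seed):
        t = planted_table()
        oracle = exhaustive_reduct(t)
        got = select_features(t, SpiralConfig(seed=seed))
        assert np.array_equal(got, oracle)

    def test_constant_attributes_rejected(self):
        t = DecisionTable(X=np.zeros((10, 3), dtype=int),
                          d=np.array([0, 1] * 5))
        with pytest.raises(ValueError):
            select_features(t, SpiralConfig(seed=0))

    def test_transformer_interface(self):
        rng = np.random.default_rng(2)
        X = rng.random((80, 6))
        y = (X[:, 0] > 0.5).astype(int)
        sel = lc.SpiralRoughSetSelector(k_max=30, random_state=0).fit(X, y)
        assert sel.get_support().any()
        assert sel.transform(X).shape == (80, sel.get_support().sum())

    def test_fifty_feature_table_selects_compact_subset(self):
        # separable table at the pipeline's scale: the selector should come
        # back with far fewer than the full 50 attributes
        rng = np.random.default_rng(4)
        n = 120
        informative = rng.integers(0, 4, (n, 2))
        d = (informative.sum(axis=1) > 3).astype(int)
        X = np.column_stack([informative, rng.integers(0, 4, (n, 48))])
        t = DecisionTable(X=X, d=d)
        mask = select_features(t, SpiralConfig(seed=0, k_max=40))
        assert mask.sum() <= 25


class TestDiscretize:
    def test_equal_frequency_bins_reusable_on_heldout(self):
        rng = np.random.default_rng(0)
        X = rng.random((100, 3))
        t, edges = discretize_table(X, rng.integers(0, 2, 100), bins=4)
        assert t.X.max() <= 3
        t2, _ = discretize_table(X[:10], np.zeros(10, int), edges=edges)
        assert np.array_equal(t2.X, t.X[:10])
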