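import numpy as np
import pytest
import scipy.stats

import rggc
from rggc.graph import (
    build_graph,
    compute_S,
    compute_W,
    default_lambda,
    ridge_oracle,
)


def unit_columns(rng, p, n):
    X = rng.normal(size=(p, n))
    return X / np.linalg.norm(X, axis=0, keepdims=True)


def two_cell_matrix(c: float, p: int = 50) -> np.ndarray:
    """Two unit-norm columns with inner product exactly c."""
    x1 = np.zeros(p)
    x1[0] = 1.0
    x2 = np.zeros(p)
    x2[0] = c
    x2[1] = np.sqrt(1 - c**2)
    return np.column_stack([x1, x2])


class TestDefaultLambda:
    def test_aic(self):
        assert default_lambda(5000, "aic") == 2.0

    def test_bic_is_log_gene_count(self):
        assert default_lambda(5000, "bic") == pytest.approx(8.517193, abs=1e-6)

    def test_custom(self):
        assert default_lambda(10, "custom", 0.1) == 0.1

    def test_custom_requires_value(self):
        with pytest.raises(ValueError):
            default_lambda(10, "custom")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            default_lambda(10, "custom", -1.0)


class TestComputeS:
    def test_orthonormal_columns(self):
        X = np.eye(6)[:, :3]
        np.testing.assert_allclose(compute_S(X, 1.0), 0.5 * np.eye(3), atol=1e-12)

    def test_two_cell_hand_inverse(self):
        # Gram + I = [[2, .8], [.8, 2]]; inverse = [[2,-.8],[-.8,2]]/(4-.64)
        S = compute_S(two_cell_matrix(0.8), 1.0)
        expected = np.array([[2, -0.8], [-0.8, 2]]) / (4 - 0.64)
        np.testing.assert_allclose(S, expected, atol=1e-12)
        np.testing.assert_allclose(S[0, 0], 0.5952, atol=1e-4)
        np.testing.assert_allclose(S[0, 1], -0.2381, atol=1e-4)

    def test_inverse_property(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 8))
        lam = 2.0
        S = compute_S(X, lam)
        G = X.T @ X + lam * np.eye(8)
        np.testing.assert_allclose(S @ G, np.eye(8), atol=1e-6)

    def test_large_lambda_limit(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        np.testing.assert_allclose(1e12 * compute_S(X, 1e12), np.eye(5), atol=1e-6)

    def test_singular_without_regularization(self):
        X = np.ones((3, 5))  # rank 1, n > p
        with pytest.raises(np.linalg.LinAlgError, match="positive lambda"):
            compute_S(X, 0.0)


class TestClosedForm:
    @pytest.mark.parametrize("lam", [0.1, 2.0, 100.0])
    def test_identity_I_minus_lambda_S(self, lam):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(30, 12))
        S = compute_S(X, lam)
        G = X.T @ X
        direct = np.linalg.solve(G + lam * np.eye(12), G)
        np.testing.assert_allclose(direct, np.eye(12) - lam * S, atol=1e-8)

    def test_matches_unconstrained_ridge_per_column(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 10))
        lam = 1.5
        S = compute_S(X, lam)
        Wfull = np.eye(10) - lam * S
        for j in range(10):
            wj = np.linalg.solve(X.T @ X + lam * np.eye(10), X.T @ X[:, j])
            np.testing.assert_allclose(Wfull[:, j], wj, atol=1e-8)


class TestComputeW:
    def test_two_cell_symmetric_normalization(self):
        # -s12/sqrt(s11 s22) = 0.2381/0.5952 = 0.4 for c=0.8, lam=1
        S = compute_S(two_cell_matrix(0.8), 1.0)
        model = compute_W(S, 1.0, normalization="symmetric", clip_negative=False)
        assert model.W[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_orthonormal_gives_no_edges(self):
        X = np.eye(6)[:, :3]
        model = build_graph(X, lam=1.0, clip_negative=False)
        np.testing.assert_allclose(model.W, 0.0, atol=1e-12)

    def test_zero_diagonal_all_modes(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 6))
        S = compute_S(X, 2.0)
        for norm in ("none", "column", "symmetric"):
            model = compute_W(S, 2.0, normalization=norm, clip_negative=False)
            np.testing.assert_array_equal(np.diag(model.W), 0.0)

    def test_modes_match_definitions(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 6))
        lam = 2.0
        S = compute_S(X, lam)
        d = np.diag(S)
        off = ~np.eye(6, dtype=bool)
        Wn = compute_W(S, lam, "none", clip_negative=False).W
        np.testing.assert_allclose(Wn[off], (-lam * S)[off], atol=1e-12)
        Wc = compute_W(S, lam, "column", clip_negative=False).W
        np.testing.assert_allclose(Wc[off], (-S / d[None, :])[off], atol=1e-12)
        Ws = compute_W(S, lam, "symmetric", clip_negative=False).W
        expected = -S / np.sqrt(np.outer(d, d))
        np.testing.assert_allclose(Ws[off], expected[off], atol=1e-12)

    def test_partial_correlation_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.normal(size=(25, 8))
            S = compute_S(X, float(rng.uniform(0.5, 5)))
            W = compute_W(S, 1.0, "symmetric", clip_negative=False).W
            assert np.abs(W).max() < 1.0

    def test_clip_negative(self):
        rng = np.random.default_rng(8)
        S = compute_S(rng.normal(size=(15, 6)), 2.0)
        model = compute_W(S, 2.0, "symmetric", clip_negative=True)
        assert (model.W >= 0).all()

    def test_column_mode_symmetrize(self):
        rng = np.random.default_rng(9)
        model = build_graph(rng.normal(size=(15, 6)), lam=2.0,
                            normalization="column", clip_negative=False)
        np.testing.assert_allclose(model.W, model.W.T, atol=1e-12)

    def test_monotone_in_inner_product(self):
        vals = [compute_W(compute_S(two_cell_matrix(c), 1.0), 1.0,
                          "symmetric", clip_negative=False).W[0, 1]
                for c in np.linspace(0.05, 0.95, 10)]
        assert (np.diff(vals) > 0).all()

    def test_nonpositive_diagonal_rejected(self):
        S = np.array([[1.0, 0.0], [0.0, -0.5]])
        with pytest.raises(np.linalg.LinAlgError):
            compute_W(S, 1.0)


class TestRidgeOracle:
    def test_minimizes_objective(self):
        rng = np.random.default_rng(10)
        X = unit_columns(rng, 30, 8)
        lam = 1.0
        j = 2
        w = ridge_oracle(X, lam, j)
        assert w[j] == 0.0

        def objective(v):
            return np.sum((X[:, j] - X @ v) ** 2) + lam * np.sum(v**2)

        base = objective(w)
        for _ in range(50):
            v = w + rng.normal(scale=0.01, size=8)
            v[j] = 0.0
            assert objective(v) >= base - 1e-12

    def test_objective_at_most_norm_of_target(self):
        rng = np.random.default_rng(11)
        X = unit_columns(rng, 40, 10)
        for j in range(10):
            w = ridge_oracle(X, 2.0, j)
            obj = np.sum((X[:, j] - X @ w) ** 2) + 2.0 * np.sum(w**2)
            assert obj <= 1.0 + 1e-12

    def test_shrinkage_limit(self):
        rng = np.random.default_rng(12)
        X = unit_columns(rng, 30, 6)
        w = ridge_oracle(X, 1e10, 0)
        np.testing.assert_allclose(w, 0.0, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.5, 2.0, 10.0])
    def test_grouping_effect_bound(self, lam):
        rng = np.random.default_rng(13)
        X = unit_columns(rng, 50, 9)
        for j in range(9):
            w = ridge_oracle(X, lam, j)
            for k in range(9):
                for l in range(k + 1, 9):
                    if j in (k, l):
                        continue
                    bound = np.sqrt(2 * (1 - X[:, k] @ X[:, l])) / lam
                    assert abs(w[k] - w[l]) <= bound + 1e-10


class TestGroupingEffectInW:
    def test_duplicated_cells_equal_coefficients(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 7))
        X[:, 4] = X[:, 2]  # duplicate a cell
        model = build_graph(X, lam=2.0, normalization="none", clip_negative=False)
        W = model.W
        for j in range(7):
            if j in (2, 4):
                continue
            assert W[2, j] == pytest.approx(W[4, j], abs=1e-10)


class TestLambdaRankRobustness:
    """Clusters depend on the relative, not absolute, edge weights: the
    entrywise rank order of W is nearly invariant to the regularization
    strength, which is why no lambda tuning is needed."""

    def test_rank_order_stable_across_lambda(self):
        # full benchmark-design scale: the property strengthens with both
        # the gene/cell ratio and the cell count
        counts, _ = rggc.simulate_counts(rggc.presets()["simdata1"].with_seed(1))
        X = rggc.preprocess(counts)
        off = ~np.eye(X.n_cells, dtype=bool)

        def w_off(lam):
            return build_graph(X, lam=lam, normalization="none",
                               clip_negative=False).W[off]

        # near-perfect across two decades bracketing both defaults (2, ln p)
        rho_mid = scipy.stats.spearmanr(w_off(1.0), w_off(100.0)).statistic
        assert rho_mid > 0.99
        # still strongly concordant at the extremes of the published grid,
        # where S shifts from a partial- to a marginal-correlation structure
        rho_ext = scipy.stats.spearmanr(w_off(0.01), w_off(1000.0)).statistic
        assert rho_ext > 0.9
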