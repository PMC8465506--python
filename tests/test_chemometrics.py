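import numpy as np
import pytest

from ovofresh import (ValidationError, loo_rmsecv, pca_fit, pca_transform,
                      pearson_r, pls_fit, pls_predict, rmsep)


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self, rng):
        shape = rng.normal(size=30)
        X = np.outer(rng.normal(size=12), shape) + rng.normal(size=30)
        model = pca_fit(X, 3)
        assert model.explained_ratio[0] == pytest.approx(1.0)
        assert model.explained_ratio[1:] == pytest.approx(0.0, abs=1e-12)

    def test_agreement_with_dense_eigendecomposition(self, rng):
        """Loadings/variances must match a brute-force covariance
        eigensolver (independent route) up to component sign."""
        for _ in range(5):
            X = rng.normal(size=(10, 8))
            model = pca_fit(X, 5)
            C = np.cov(X, rowvar=False, ddof=1)
            evals, evecs = np.linalg.eigh(C)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            np.testing.assert_allclose(model.explained_ratio,
                                       evals[:5] / evals.sum(), atol=1e-10)
            for j in range(5):
                dot = abs(evecs[:, j] @ model.loadings[:, j])
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal_and_ratios_sorted(self, rng):
        model = pca_fit(rng.normal(size=(20, 15)), 6)
        G = model.loadings.T @ model.loadings
        np.testing.assert_allclose(G, np.eye(6), atol=1e-8)
        assert np.all(np.diff(model.explained_ratio) <= 1e-12)
        assert model.explained_ratio.sum() <= 1 + 1e-9

    def test_total_variance_conserved(self, rng):
        X = rng.normal(size=(12, 7))
        model = pca_fit(X, min(12 - 1, 7))
        assert model.explained_ratio.sum() == pytest.approx(1.0)

    def test_transform_of_training_mean_is_zero(self, rng):
        X = rng.normal(size=(9, 12))
        model = pca_fit(X, 4)
        np.testing.assert_allclose(
            pca_transform(model, X.mean(axis=0)[None, :]), 0.0, atol=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(8, 5))
        model = pca_fit(X, 5)
        scores = pca_transform(model, X)
        np.testing.assert_allclose(scores @ model.loadings.T,
                                   X - model.mean_spectrum, atol=1e-8)

    def test_duplicated_rows_share_scores(self, rng):
        X = rng.normal(size=(6, 10))
        X[3] = X[0]
        scores = pca_transform(pca_fit(X, 2), X)
        np.testing.assert_allclose(scores[0], scores[3])

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError):
            pca_fit(np.full((5, 4), 2.0), 2)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValidationError):
            pca_fit(rng.normal(size=(5, 10)), 5)


class TestPLS:
    def test_univariate_single_lv_equals_ols(self, rng):
        """With one predictor, a 1-LV PLS fit is ordinary least squares:
        slope = cov(x, y)/var(x)."""
        x = rng.normal(size=25)
        y = 2.5 * x + rng.normal(size=25)
        model = pls_fit(x[:, None], y, 1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.regression_vector[0] == pytest.approx(slope)
        x_new = np.array([[-1.3], [0.0], [2.2]])
        expected = y.mean() + slope * (x_new.ravel() - x.mean())
        np.testing.assert_allclose(pls_predict(model, x_new), expected)

    def test_exact_interpolation_at_full_rank(self, rng):
        X = rng.normal(size=(12, 6))
        beta = rng.normal(size=6)
        y = X @ beta + 1.0
        model = pls_fit(X, y, 6)
        np.testing.assert_allclose(pls_predict(model, X), y, atol=1e-8)

    def test_agreement_with_reference_implementation(self, rng):
        """Independent oracle: scikit-learn's PLS regression on random
        20 x 50 problems, at several LV counts."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for trial in range(3):
            X = rng.normal(size=(20, 50))
            y = X[:, :5] @ rng.normal(size=5) + 0.3 * rng.normal(size=20)
            for k in (1, 4, 8):
                mine = pls_predict(pls_fit(X, y, k), X)
                ref = sklearn.PLSRegression(n_components=k, scale=False) \
                    .fit(X, y).predict(X).ravel()
                np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(15, 30))
        y = rng.normal(size=15)
        model = pls_fit(X, y, 5)
        Xc = X - model.x_mean
        # reconstruct scores sequentially through deflation
        T = []
        Xd = Xc.copy()
        for a in range(model.n_lv):
            t = Xd @ model.weights[:, a]
            Xd = Xd - np.outer(t, model.x_loadings[:, a])
            T.append(t)
        T = np.column_stack(T)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_regression_vector_equals_sequential_prediction(self, rng):
        X = rng.normal(size=(10, 20))
        y = rng.normal(size=10)
        model = pls_fit(X, y, 4)
        Xn = rng.normal(size=(5, 20))
        seq = np.full(5, model.y_mean)
        Xd = Xn - model.x_mean
        for a in range(model.n_lv):
            t = Xd @ model.weights[:, a]
            seq = seq + t * model.y_loadings[a]
            Xd = Xd - np.outer(t, model.x_loadings[:, a])
        np.testing.assert_allclose(pls_predict(model, Xn), seq, atol=1e-8)

    def test_training_rmse_non_increasing_in_lv(self, rng):
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        errs = [rmsep(y, pls_predict(pls_fit(X, y, k), X))
                for k in range(1, 9)]
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_prediction_linearity(self, rng):
        X = rng.normal(size=(12, 8))
        model = pls_fit(X, rng.normal(size=12), 3)
        x1, x2 = rng.normal(size=(2, 8))
        a = 0.3
        mix = pls_predict(model, (a * x1 + (1 - a) * x2)[None, :])[0]
        parts = pls_predict(model, np.vstack([x1, x2]))
        assert mix == pytest.approx(a * parts[0] + (1 - a) * parts[1])

    def test_centered_test_row_predicts_mean(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = pls_fit(X, y, 2)
        assert pls_predict(model, model.x_mean[None, :])[0] \
            == pytest.approx(model.y_mean)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValidationError):
            pls_fit(rng.normal(size=(8, 5)), np.ones(8), 2)


class TestLooRmsecv:
    def test_equals_brute_force_refits(self, rng):
        """The vectorized cross-validation must agree with a naive loop
        that rebuilds every fold's model from scratch."""
        X = rng.normal(size=(14, 10))
        y = X[:, :3] @ rng.normal(size=3) + 0.2 * rng.normal(size=14)
        max_lv = 6
        n = len(y)
        errs = np.zeros((n, max_lv))
        for i in range(n):
            keep = np.arange(n) != i
            for k in range(1, max_lv + 1):
                m = pls_fit(X[keep], y[keep], k)
                errs[i, k - 1] = pls_predict(m, X[i:i + 1])[0] - y[i]
        brute = np.sqrt((errs ** 2).mean(axis=0))
        np.testing.assert_allclose(loo_rmsecv(X, y, max_lv), brute,
                                   atol=1e-8)

    def test_constant_response_gives_zero_error(self):
        X = np.arange(24, dtype=float).reshape(8, 3) ** 1.5
        np.testing.assert_allclose(loo_rmsecv(X, np.full(8, 3.3), 2), 0.0,
                                   atol=1e-12)

    def test_overfitting_visible_at_absurd_lv(self, rng):
        """On low-rank signal data, RMSECV at a grossly excessive LV
        count exceeds RMSECV at the planted dimensionality."""
        n, p, rank = 30, 40, 2
        scores = rng.normal(size=(n, rank))
        X = scores @ rng.normal(size=(rank, p)) + 0.05 * rng.normal(size=(n, p))
        y = scores @ np.array([1.0, -0.7]) + 0.05 * rng.normal(size=n)
        curve = loo_rmsecv(X, y, 20)
        assert curve[19] > curve[rank - 1]

    def test_max_lv_bounds_enforced(self, rng):
        with pytest.raises(ValidationError):
            loo_rmsecv(rng.normal(size=(6, 8)), rng.normal(size=6), 5)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmsep(y, y) == 0.0
        assert pearson_r(y, y) == pytest.approx(1.0)

    def test_symmetric_unit_errors(self):
        assert rmsep(np.array([1.0, 2.0]), np.array([2.0, 1.0])) \
            == pytest.approx(1.0)

    def test_anticorrelation(self):
        y = np.array([-1.0, 0.0, 2.0])
        assert pearson_r(y, -y) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
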