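import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from chlorospec import fit_plsr, important_bands, predict_plsr, vip_scores


def latent_factor_data(rng, n=60, p=12, rank=2, noise=0.0):
    T = rng.normal(size=(n, rank))
    P = rng.normal(size=(rank, p))
    X = T @ P + noise * rng.normal(size=(n, p))
    y = T @ rng.normal(size=rank) + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_exact_univariate_line_recovered_with_one_lv(self):
        X = np.linspace(0.0, 1.0, 12).reshape(-1, 1)
        y = 2.0 * X.ravel()
        m = fit_plsr(X, y, max_lv=1)
        assert m.n_lv == 1
        assert m.coef[0] == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(predict_plsr(m, X), y, atol=1e-10)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant response"):
            fit_plsr(rng.normal(size=(10, 3)), np.ones(10))

    def test_constant_predictors_rejected(self, rng):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="constant"):
            fit_plsr(X, rng.normal(size=10))

    def test_max_lv_clipped_to_rank_with_warning(self, rng):
        X, y = latent_factor_data(rng, n=8, p=3)
        with pytest.warns(UserWarning, match="clip"):
            m = fit_plsr(X, y, max_lv=10)
        assert m.n_lv <= 3

    def test_noiseless_low_rank_data_recovered(self, rng):
        X, y = latent_factor_data(rng, n=50, p=10, rank=2)
        m = fit_plsr(X, y, max_lv=6)
        assert m.n_lv <= 3
        resid = predict_plsr(m, X) - y
        assert np.sqrt(np.mean(resid**2)) < 1e-8

    def test_chosen_lv_minimises_loo_rmse(self, rng):
        X, y = latent_factor_data(rng, n=30, p=8, rank=3, noise=0.1)
        m = fit_plsr(X, y, max_lv=6)
        assert m.cv_rmse_by_lv[m.n_lv - 1] == m.cv_rmse_by_lv.min()

    def test_full_rank_pls_reproduces_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + 0.1 * rng.normal(size=40)
        m = fit_plsr(X, y, max_lv=5)
        A = np.column_stack([np.ones(40), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        ols_pred = A @ beta
        # with all latent variables the PLS predictor spans the full
        # column space, matching OLS: B = W (P'W)^{-1} q
        W, P, q = m.weights, m.x_loadings, m.y_loadings
        coef_full = W @ np.linalg.solve(P.T @ W, q)
        pred_full = m.y_mean + (X - m.x_mean) @ coef_full
        np.testing.assert_allclose(pred_full, ols_pred, atol=1e-6)

    def test_score_vectors_mutually_orthogonal(self, rng):
        X, y = latent_factor_data(rng, n=40, p=15, rank=4, noise=0.05)
        m = fit_plsr(X, y, max_lv=5)
        T = m.x_scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_x_residual_orthogonal_to_scores(self, rng):
        """Deflation correctness: X - T P' is orthogonal to every score."""
        X, y = latent_factor_data(rng, n=40, p=15, rank=4, noise=0.05)
        m = fit_plsr(X, y, max_lv=5)
        Xc = X - m.x_mean
        resid = Xc - m.x_scores @ m.x_loadings.T
        assert np.abs(m.x_scores.T @ resid).max() < 1e-8


class TestPredict:
    def test_prediction_is_affine(self, rng):
        X, y = latent_factor_data(rng, n=30, p=8, rank=2, noise=0.1)
        m = fit_plsr(X, y, max_lv=4)
        X1, X2 = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
        alpha = 0.3
        lhs = predict_plsr(m, alpha * X1 + (1 - alpha) * X2)
        rhs = alpha * predict_plsr(m, X1) + (1 - alpha) * predict_plsr(m, X2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_wavelength_count_mismatch_rejected(self, rng):
        X, y = latent_factor_data(rng)
        m = fit_plsr(X, y, max_lv=3)
        with pytest.raises(ValueError, match="mismatch"):
            predict_plsr(m, rng.normal(size=(3, 5)))

    def test_matches_sklearn_pls_at_fixed_component_count(self, rng):
        """Independent cross-check: our NIPALS coefficient path equals
        scikit-learn's PLSRegression (unscaled) at the same LV count."""
        X, y = latent_factor_data(rng, n=45, p=20, rank=5, noise=0.2)
        m = fit_plsr(X, y, max_lv=4)
        sk = PLSRegression(n_components=m.n_lv, scale=False).fit(X, y)
        Xnew = rng.normal(size=(10, 20))
        np.testing.assert_allclose(
            predict_plsr(m, Xnew), sk.predict(Xnew).ravel(), atol=1e-6
        )


class TestVIP:
    def test_single_predictor_has_vip_one(self):
        X = np.linspace(0, 1, 10).reshape(-1, 1)
        m = fit_plsr(X, 3 * X.ravel() + 1, max_lv=1)
        assert vip_scores(m)[0] == pytest.approx(1.0, abs=1e-12)

    def test_mean_squared_vip_is_one(self, rng):
        X, y = latent_factor_data(rng, n=40, p=25, rank=3, noise=0.1)
        m = fit_plsr(X, y, max_lv=5)
        assert np.mean(vip_scores(m) ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_vip_nonnegative(self, rng):
        X, y = latent_factor_data(rng, n=30, p=10, rank=2, noise=0.3)
        m = fit_plsr(X, y, max_lv=4)
        assert (vip_scores(m) >= 0).all()


class TestImportantBands:
    wl = np.arange(500.0, 700.0, 10.0)

    def test_nothing_above_threshold_gives_empty_list(self):
        assert important_bands(np.full(20, 0.5), self.wl) == []

    def test_single_run_yields_single_interval(self):
        vip = np.where((self.wl >= 550) & (self.wl <= 600), 1.5, 0.5)
        assert important_bands(vip, self.wl) == [(550.0, 600.0)]

    def test_nearby_runs_merge_within_gap(self):
        vip = np.full(20, 0.5)
        vip[2:4] = 1.5   # 520-530
        vip[6:8] = 1.5   # 560-570
        separate = important_bands(vip, self.wl, merge_gap_nm=5.0)
        merged = important_bands(vip, self.wl, merge_gap_nm=40.0)
        assert separate == [(520.0, 530.0), (560.0, 570.0)]
        assert merged == [(520.0, 570.0)]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            important_bands(np.ones(5), self.wl)
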