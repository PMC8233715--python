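"""NIPALS PLS: exactness, oracles, factor selection, Hotelling screening."""

import numpy as np
import pytest

import nirspec_fa as nf
from nirspec_fa import pls
from nirspec_fa.errors import DegenerateTargetError


def _random_problem(rng, n=30, p=12, noise=0.05):
    X = rng.standard_normal((n, p))
    b = rng.standard_normal(p)
    y = X @ b + noise * rng.standard_normal(n)
    return X, y


class TestFit:
    def test_single_latent_direction_exact_at_one_factor(self, rng):
        t = rng.standard_normal(25)
        p_load = rng.standard_normal(10)
        X = np.outer(t, p_load)
        y = 3.0 * t + 1.0
        model = pls.fit_pls(X, y, 1)
        resid = y - model.predict(X)
        assert np.abs(resid).max() < 1e-9
        assert nf.r_squared(y, model.predict(X)) > 1 - 1e-12

    def test_full_rank_equals_ols_oracle(self, rng):
        X = rng.standard_normal((20, 15))
        y = rng.standard_normal(20)
        model = pls.fit_pls(X, y, 15)
        Xc = X - X.mean(axis=0)
        b_ols, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        oracle = y.mean() + Xc @ b_ols
        np.testing.assert_allclose(model.predict(X), oracle, atol=1e-6)

    def test_sample_order_invariance(self, rng):
        X, y = _random_problem(rng)
        perm = rng.permutation(len(y))
        m1 = pls.fit_pls(X, y, 4)
        m2 = pls.fit_pls(X[perm], y[perm], 4)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-10)

    def test_constant_target_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(DegenerateTargetError):
            pls.fit_pls(X, np.full(10, 2.0), 2)

    def test_agrees_with_sklearn_pls(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_problem(rng, n=40, p=25, noise=0.1)
        model = pls.fit_pls(X, y, 5)
        sk = sklearn.PLSRegression(n_components=5, scale=False)
        sk.fit(X, y.reshape(-1, 1))
        np.testing.assert_allclose(
            model.predict(X), sk.predict(X).ravel(), atol=1e-8
        )

    def test_scores_orthogonal_and_sse_nonincreasing(self, rng):
        X, y = _random_problem(rng, n=40, p=15)
        model = pls.fit_pls(X, y, 8)
        T = model.scores(X)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()
        sse = [np.sum((y - pls.fit_pls(X, y, F).predict(X)) ** 2)
               for F in range(1, 9)]
        assert all(a >= b - 1e-10 for a, b in zip(sse, sse[1:]))

    def test_coefficient_recovery_at_high_snr(self, rng):
        n, p = 200, 40
        X = rng.standard_normal((n, p))
        b_true = rng.standard_normal(p)
        signal = X @ b_true
        y = signal + signal.std() / 100.0 * rng.standard_normal(n)
        model = pls.fit_pls(X, y, p)
        corr = np.corrcoef(model.coef, b_true)[0, 1]
        assert corr > 0.99


class TestPredict:
    def test_calibration_mean_maps_to_y_mean(self, rng):
        X, y = _random_problem(rng)
        model = pls.fit_pls(X, y, 3)
        pred = model.predict(X.mean(axis=0))
        np.testing.assert_allclose(pred, y.mean(), atol=1e-10)

    def test_prediction_is_affine(self, rng):
        X, y = _random_problem(rng)
        model = pls.fit_pls(X, y, 3)
        x1, x2 = X[0], X[1]
        alpha = 0.3
        mix = model.predict(alpha * x1 + (1 - alpha) * x2)
        parts = alpha * model.predict(x1) + (1 - alpha) * model.predict(x2)
        np.testing.assert_allclose(mix, parts, atol=1e-10)

    def test_y_scale_equivariance(self, rng):
        X, y = _random_problem(rng)
        m1 = pls.fit_pls(X, y, 3)
        m2 = pls.fit_pls(X, 1000.0 * y, 3)
        np.testing.assert_allclose(1000.0 * m1.predict(X), m2.predict(X),
                                   rtol=1e-10)

    def test_shape_mismatch(self, rng):
        X, y = _random_problem(rng)
        model = pls.fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="wavelengths"):
            model.predict(np.zeros((3, 5)))


class TestFactorSelection:
    def test_noiseless_rank_two_system_resolves_to_two(self):
        rng = np.random.default_rng(42)
        t1, t2 = rng.standard_normal((2, 80))
        X = (np.outer(t1, rng.standard_normal(30))
             + np.outer(t2, rng.standard_normal(30)))
        y = t1 - 3.0 * t2
        assert pls.select_factors(X, y, 10, seed=0) == 2

    def test_pure_noise_resolves_to_one(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 30))
        y = rng.standard_normal(60)
        assert pls.select_factors(X, y, 10, seed=0) == 1

    def test_deterministic_given_seed(self, rng):
        X, y = _random_problem(rng, n=50, p=20, noise=0.5)
        picks = {pls.select_factors(X, y, 8, seed=3) for _ in range(3)}
        assert len(picks) == 1


class TestHotelling:
    def test_centroid_has_zero_h(self, rng):
        X, y = _random_problem(rng)
        model = pls.fit_pls(X, y, 3)
        res = pls.hotelling_h(model, X.mean(axis=0)[None, :])
        assert res.h[0] < 1e-18

    def test_mean_h_identity(self, rng):
        X, y = _random_problem(rng, n=35, p=10)
        F = 4
        model = pls.fit_pls(X, y, F)
        res = pls.hotelling_h(model, X)
        n = len(y)
        assert abs(res.h.mean() - F * (n - 1) / n) < 1e-8

    def test_no_flags_below_threshold(self, rng):
        X, y = _random_problem(rng)
        model = pls.fit_pls(X, y, 2)
        res = pls.hotelling_h(model, X, threshold=1e6)
        assert res.n_outliers == 0
        assert np.all(res.outlier_flags == (res.h > res.threshold))


class TestOutlierRemoval:
    def test_clean_data_keeps_model(self, rng):
        X, y = _random_problem(rng, n=25, p=8)
        model, removed = pls.remove_outliers_refit(X, y, 2, threshold=1e6)
        plain = pls.fit_pls(X, y, 2)
        assert removed.size == 0
        np.testing.assert_array_equal(model.coef, plain.coef)

    def test_gross_outlier_removed_and_sec_improves(self, rng):
        X, y = _random_problem(rng, n=40, p=12, noise=0.01)
        X_bad = X.copy()
        X_bad[7] = X[7] * 50.0  # gross spectral artefact
        model, removed = pls.remove_outliers_refit(X_bad, y, 3, threshold=10.0)
        assert 7 in removed
        keep = np.setdiff1d(np.arange(40), removed)
        sec_after = nf.sec(y[keep], model.predict(X_bad[keep]), 3)
        naive = pls.fit_pls(X_bad, y, 3)
        sec_before = nf.sec(y, naive.predict(X_bad), 3)
        assert sec_after < sec_before

    def test_refusal_when_too_few_left(self, rng):
        X, y = _random_problem(rng, n=8, p=5)
        with pytest.warns(UserWarning, match="too few"):
            model, removed = pls.remove_outliers_refit(X, y, 3, threshold=1e-6)
        assert removed.size == 0
        np.testing.assert_array_equal(model.coef, pls.fit_pls(X, y, 3).coef)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X, y = _random_problem(rng)
        model = pls.fit_pls(X, y, 3, meta={"analyte": "TotalFA"})
        path = tmp_path / "model.json"
        model.save_json(path)
        back = pls.PLSModel.load_json(path)
        np.testing.assert_array_equal(model.predict(X), back.predict(X))
        assert back.meta["analyte"] == "TotalFA"
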