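import numpy as np
import pytest

from glyco import impute
from glyco.impute import (LaggedMatrix, build_lagged_matrix, fit_ppca,
                          impute_basal, impute_cgm_ppca, impute_sparse_median)

from conftest import make_series


def series_with_cgm(cgm, **kw):
    defaults = dict(basal_rate=0.5, bolus=0.0, carbohydrate=0.0,
                    energy_value=0.0, activity_duration=0.0)
    defaults.update(kw)
    return make_series(len(cgm), cgm=np.asarray(cgm, float), **defaults)


class TestRuleBased:
    def test_basal_no_gaps_identity(self):
        s = make_series(50, basal_rate=np.full(50, 1.2))
        out = impute_basal(s)
        np.testing.assert_array_equal(out.channels["basal_rate"],
                                      s.channels["basal_rate"])

    def test_basal_short_gap_forward_filled(self):
        b = np.full(50, 1.2)
        b[10:16] = np.nan
        out = impute_basal(make_series(50, basal_rate=b))
        np.testing.assert_array_equal(out.channels["basal_rate"], 1.2)
        assert (out.provenance["basal_rate"][10:16] == 2).all()

    def test_basal_long_gap_uses_previous_day(self):
        n = 2 * 288 + 50
        b = np.tile(np.r_[np.full(144, 0.8), np.full(144, 1.1)], 3)[:n]
        expect = b.copy()
        start = 288 + 100
        b[start:start + 30] = np.nan  # 30-sample gap: > 2 h
        out = impute_basal(make_series(n, basal_rate=b))
        # index-shift oracle: the gap takes the values 288 samples earlier
        np.testing.assert_array_equal(
            out.channels["basal_rate"][start:start + 30],
            expect[start - 288:start - 288 + 30])

    def test_median_sparse_mostly_zero(self):
        x = np.full(20, np.nan)
        x[:4] = 0.0
        x[4] = 45.0
        out = impute_sparse_median(make_series(20, carbohydrate=x), "carbohydrate")
        assert (out.channels["carbohydrate"][5:] == 0.0).all()

    def test_median_all_observed_identity(self):
        x = np.arange(10.0)
        out = impute_sparse_median(make_series(10, bolus=x), "bolus")
        np.testing.assert_array_equal(out.channels["bolus"], x)

    def test_median_value_by_sorting_oracle(self):
        x = np.array([2.0, np.nan, 4.0, np.nan, 6.0])
        out = impute_sparse_median(make_series(5, smbg=x), "smbg")
        assert out.channels["smbg"][1] == sorted([2, 4, 6])[1]
        assert out.channels["smbg"][3] == 4.0


class TestLaggedMatrix:
    def test_shape_and_obs_count_fully_observed(self):
        s = series_with_cgm(np.linspace(100, 130, 30))
        L = build_lagged_matrix(s)
        assert (L.M, L.N) == (125, 6)
        assert L.obs_mask().sum() == 750

    def test_missing_cgm_absent_from_all_occurrences(self):
        cgm = np.linspace(100, 130, 40)
        g = 30
        cgm[g] = np.nan
        L = build_lagged_matrix(series_with_cgm(cgm))
        # independent scan: occurrences of grid sample g are (lag, g+lag-24)
        for lag in range(25):
            c = g + lag - 24
            if 0 <= c < L.N:
                assert np.isnan(L.X[lag, c])
        assert np.isnan(L.X).sum() == sum(1 for lag in range(25)
                                          if 0 <= g + lag - 24 < L.N)

    def test_constant_channels_give_constant_rows(self):
        L = build_lagged_matrix(series_with_cgm(np.full(30, 120.0)))
        assert (np.ptp(L.X, axis=1) == 0).all()

    def test_short_series_is_error(self):
        with pytest.raises(ValueError):
            build_lagged_matrix(series_with_cgm(np.full(20, 120.0)))


def simulate_ppca_data(M=30, N=200, q=3, sigma=0.3, seed=0):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((M, q))
    T = rng.standard_normal((q, N))
    mu = rng.standard_normal(M)
    X = W @ T + mu[:, None] + rng.standard_normal((M, N)) * sigma
    return X, W, mu, sigma


def subspace_angle_deg(A, B):
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s.min(), -1, 1)))


class TestPPCA:
    def test_recovers_noise_and_subspace(self):
        X, W, mu, sigma = simulate_ppca_data()
        model = fit_ppca(LaggedMatrix(X=X), q=3, tol=1e-8, max_iter=2000, seed=1)
        assert model.sigma2 == pytest.approx(sigma ** 2, rel=0.10)
        assert subspace_angle_deg(model.W, W) < 5.0

    def test_complete_data_matches_pca_subspace(self):
        X, _, _, _ = simulate_ppca_data(seed=3)
        model = fit_ppca(LaggedMatrix(X=X), q=3, tol=1e-9, max_iter=3000, seed=2)
        Xc = X - X.mean(axis=1, keepdims=True)
        U = np.linalg.svd(Xc, full_matrices=False)[0][:, :3]
        assert subspace_angle_deg(model.W, U) < 1.0

    def test_zero_variance_degenerates(self):
        X = np.full((10, 50), 7.0)
        model = fit_ppca(LaggedMatrix(X=X), q=2, tol=1e-10, max_iter=200, seed=0)
        assert model.sigma2 < 1e-6
        assert np.abs(model.W).max() < 1e-3
        np.testing.assert_allclose(model.mu, 7.0)

    def test_loglik_nondecreasing_with_missing(self):
        X, _, _, _ = simulate_ppca_data(M=20, N=120, seed=5)
        rng = np.random.default_rng(6)
        X[rng.random(X.shape) < 0.15] = np.nan
        model = fit_ppca(LaggedMatrix(X=X), q=3, tol=1e-9, max_iter=150, seed=7,
                         track_loglik=True)
        ll = np.array(model.loglik_trace)
        assert len(ll) > 5
        assert np.all(np.diff(ll) > -1e-6 * np.abs(ll[:-1]))


class TestCgmImputation:
    def test_no_missing_is_identity(self):
        s = series_with_cgm(120 + 20 * np.sin(np.arange(60) / 5))
        out, model = impute_cgm_ppca(s, q=5, seed=0)
        assert model is None
        np.testing.assert_array_equal(out.channels["cgm"], s.channels["cgm"])

    def test_masked_recovery_rmse_below_twice_noise(self):
        rng = np.random.default_rng(8)
        n = 500
        t = np.arange(n)
        clean = 140 + 30 * np.sin(2 * np.pi * t / 36)  # 3-hour period
        noise_sd = 3.0
        cgm = clean + rng.normal(0, noise_sd, n)
        holes = rng.choice(np.arange(30, n - 5), size=10, replace=False)
        masked = cgm.copy()
        masked[holes] = np.nan
        s = series_with_cgm(masked)
        out, _ = impute_cgm_ppca(s, q=6, tol=1e-6, max_iter=300, seed=9)
        rec = out.channels["cgm"][holes]
        assert not np.isnan(rec).any()
        rmse = np.sqrt(np.mean((rec - cgm[holes]) ** 2))
        assert rmse < 2 * noise_sd

    def test_long_gap_stays_missing(self):
        cgm = 140 + 30 * np.sin(2 * np.pi * np.arange(300) / 36)
        cgm[100:130] = np.nan  # 30 consecutive samples
        out, _ = impute_cgm_ppca(series_with_cgm(cgm), q=5, seed=0)
        assert np.isnan(out.channels["cgm"][100:130]).all()

    def test_observed_samples_bit_identical(self):
        rng = np.random.default_rng(10)
        cgm = 140 + 30 * np.sin(2 * np.pi * np.arange(200) / 36)
        cgm[rng.choice(200, 8, replace=False)] = np.nan
        s = series_with_cgm(cgm)
        before = s.channels["cgm"].copy()
        out, _ = impute_cgm_ppca(s, q=5, seed=0)
        obs = ~np.isnan(before)
        np.testing.assert_array_equal(out.channels["cgm"][obs], before[obs])

    def test_monotone_information(self):
        """Adding observed cells never hurts held-out recovery on average."""
        rng0 = np.random.default_rng(11)
        n = 300
        clean = 140 + 30 * np.sin(2 * np.pi * np.arange(n) / 36)
        holes = rng0.choice(np.arange(30, n - 5), size=8, replace=False)
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            cgm = clean + rng.normal(0, 3.0, n)
            sparse = cgm.copy()
            sparse[holes] = np.nan
            extra = rng.choice(np.setdiff1d(np.arange(30, n), holes), size=60,
                               replace=False)
            sparser = sparse.copy()
            sparser[extra] = np.nan

            def rmse(x):
                out, _ = impute_cgm_ppca(series_with_cgm(x), q=5, tol=1e-5,
                                         max_iter=150, seed=seed)
                rec = out.channels["cgm"][holes]
                return np.sqrt(np.nanmean((rec - cgm[holes]) ** 2))

            deltas.append(rmse(sparser) - rmse(sparse))
        assert np.mean(deltas) > -0.2  # more data helps on average
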