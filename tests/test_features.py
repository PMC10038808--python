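import numpy as np
import pytest
from scipy import stats

from glyco import features
from glyco.features import (FeatureTable, assemble_features,
                            backward_derivatives, deviance_filter,
                            qualitative_products, sffs_select, spectral_peaks,
                            window_statistics)

from conftest import make_series


class TestDerivatives:
    def test_constant_series(self):
        d1, d2 = backward_derivatives(np.full(20, 120.0))
        np.testing.assert_allclose(d1[4:], 0.0, atol=1e-12)
        np.testing.assert_allclose(d2[5:], 0.0, atol=1e-10)

    def test_quartic_first_derivative_fourth_order(self):
        k = np.arange(25.0)
        d1, _ = backward_derivatives(k ** 4)
        # stencil error on f=k^4 is O(h^4); compare to analytic 4k^3
        for i in range(10, 21):
            assert d1[i] == pytest.approx(4 * i ** 3, rel=1e-2, abs=6.0)

    def test_quadratic_second_derivative_exact(self):
        k = np.arange(20.0)
        _, d2 = backward_derivatives(k ** 2)
        np.testing.assert_allclose(d2[5:], 2.0, atol=1e-9)

    def test_undefined_in_incomplete_windows(self):
        x = np.full(20, 120.0)
        x[7] = np.nan
        d1, d2 = backward_derivatives(x)
        assert np.isnan(d1[:4]).all()
        assert np.isnan(d1[7:12]).all()   # 5-sample window touches index 7
        assert np.isnan(d2[7:13]).all()   # 6-sample window


class TestQualitativeProducts:
    def test_examples(self):
        s, m = qualitative_products(np.array([2.0]), np.array([-3.0]))
        assert s[0] == -1 and m[0] == 6.0
        s, _ = qualitative_products(np.array([0.0]), np.array([5.0]))
        assert s[0] == 0

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        d1 = rng.standard_normal(50)
        d2 = rng.standard_normal(50)
        s, m = qualitative_products(d1, d2)
        for i in range(50):
            assert s[i] == np.sign(d1[i]) * np.sign(d2[i])
            assert m[i] == pytest.approx(abs(d1[i]) * abs(d2[i]))


class TestWindowStatistics:
    def test_constant_window_conventions(self):
        x = np.full(30, 100.0)
        names, vals = window_statistics(x, np.zeros(30), np.zeros(30), gamma=1.0)
        row = dict(zip(names, vals[29]))
        assert row["win_var"] == 0.0
        assert row["corr_cgm_d1"] == 0.0       # zero-variance convention
        assert row["ksim_d1_d2"] == 1.0        # identical vectors

    def test_window_1_to_24(self):
        x = np.concatenate([np.arange(1.0, 25.0), [np.nan]])[:24]
        names, vals = window_statistics(x, np.zeros(24), np.zeros(24), gamma=1.0)
        row = dict(zip(names, vals[23]))
        assert row["win_mean"] == pytest.approx(12.5)
        assert row["win_median"] == pytest.approx(12.5)

    def test_random_window_textbook_formulas(self):
        rng = np.random.default_rng(1)
        cgm = rng.uniform(80, 200, 40)
        d1 = rng.standard_normal(40)
        d2 = rng.standard_normal(40)
        names, vals = window_statistics(cgm, d1, d2, gamma=2.0)
        k = 39
        w = slice(16, 40)
        row = dict(zip(names, vals[k]))
        c = cgm[w]
        assert row["win_mean"] == pytest.approx(np.sum(c) / 24)
        assert row["win_var"] == pytest.approx(np.sum((c - c.mean()) ** 2) / 24)
        assert row["win_skew"] == pytest.approx(stats.skew(c))
        assert row["win_range"] == pytest.approx(c.max() - c.min())
        cov = np.mean((c - c.mean()) * (d1[w] - d1[w].mean()))
        assert row["cov_cgm_d1"] == pytest.approx(cov)
        corr = cov / (c.std() * d1[w].std())
        assert row["corr_cgm_d1"] == pytest.approx(corr)
        ks = np.exp(-np.sum((d1[w] - d2[w]) ** 2) / (2 * 4.0))
        assert row["ksim_d1_d2"] == pytest.approx(ks)


class TestSpectralPeaks:
    def test_pure_tone_three_cycles_per_day(self):
        t = np.arange(288)
        x = 140 + 25 * np.sin(2 * np.pi * 3 * t / 288)
        names, vals = spectral_peaks(x)
        row = dict(zip(names, vals[287]))
        assert row["spec_freq1"] == pytest.approx(3.0)

    def test_constant_window_all_zero(self):
        _, vals = spectral_peaks(np.full(288, 130.0))
        np.testing.assert_allclose(vals[287], 0.0)

    def test_tone_beats_noise(self):
        t = np.arange(288)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 5, 288)
            tone = noise + 20 * np.sin(2 * np.pi * 4 * t / 288)
            _, v_noise = spectral_peaks(140 + noise)
            _, v_tone = spectral_peaks(140 + tone)
            wins += v_tone[287, 0] > v_noise[287, 0]
        assert wins == 20

    def test_causality(self):
        """Features at k depend only on samples <= k."""
        rng = np.random.default_rng(2)
        x = 140 + rng.normal(0, 10, 400)
        _, full = spectral_peaks(x)
        _, trunc = spectral_peaks(x[:350])
        np.testing.assert_array_equal(full[:350], trunc)
        d1_full, _ = backward_derivatives(x)
        d1_trunc, _ = backward_derivatives(x[:350])
        np.testing.assert_array_equal(d1_full[:350], d1_trunc)


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(3)
    n = 400
    s = make_series(n, cgm=140 + 20 * np.sin(np.arange(n) / 20)
                    + rng.normal(0, 2, n),
                    basal_rate=np.full(n, 0.4), bolus=np.zeros(n))
    s.channels["cgm"][350] = np.nan
    return assemble_features(s, pic=np.full(n, 6.0), ug=np.zeros(n))


class TestAssemble:

    def test_feature_count(self, table):
        assert table.F >= 25

    def test_missing_window_invalidates_rows(self, table):
        # every row whose 288-sample window includes index 350 is invalid
        assert not table.valid_mask[350:400].any()
        assert table.valid_mask[287:350].all()

    def test_standardization_on_training_rows_only(self, table):
        train = np.zeros(len(table.values), dtype=bool)
        train[:320] = True
        std = table.standardize(train)
        sel = train & std.valid_mask
        mu = std.values[sel].mean(axis=0)
        sd = std.values[sel].std(axis=0)
        np.testing.assert_allclose(mu, 0.0, atol=1e-9)
        np.testing.assert_allclose(sd[sd > 0.5], 1.0, atol=1e-9)


def toy_classification(n=300, n_noise=6, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, n)
    signal = np.eye(4)[y] @ np.array([0.0, 1.0, 2.0, 3.0])
    cols = [signal + rng.normal(0, 0.3, n)]
    names = ["informative"]
    for j in range(n_noise):
        cols.append(rng.standard_normal(n))
        names.append(f"noise{j}")
    X = np.column_stack(cols)
    return FeatureTable(names=names, values=X,
                        valid_mask=np.ones(n, dtype=bool)), y


class TestDevianceFilter:
    def test_pure_noise_dropped_usually(self):
        drops = 0
        trials = 50
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            n = 150
            y = rng.integers(0, 4, n)
            X = rng.standard_normal((n, 1))
            tbl = FeatureTable(names=["noise"], values=X,
                               valid_mask=np.ones(n, dtype=bool))
            drops += "noise" not in deviance_filter(tbl, y, alpha=0.05)
        assert drops >= 0.9 * trials

    def test_separating_feature_retained(self):
        tbl, y = toy_classification(seed=1)
        kept = deviance_filter(tbl, y)
        assert "informative" in kept

    def test_duplicated_informative_both_retained(self):
        tbl, y = toy_classification(seed=2)
        tbl.names.append("informative_copy")
        tbl = FeatureTable(names=tbl.names,
                           values=np.column_stack([tbl.values,
                                                   tbl.values[:, 0]]),
                           valid_mask=tbl.valid_mask)
        kept = deviance_filter(tbl, y)
        assert "informative" in kept and "informative_copy" in kept

    def test_constant_feature_dropped(self):
        tbl, y = toy_classification(seed=3)
        tbl = FeatureTable(names=["const"] + tbl.names[1:],
                           values=np.column_stack([np.ones(len(y)),
                                                   tbl.values[:, 1:]]),
                           valid_mask=tbl.valid_mask)
        assert "const" not in deviance_filter(tbl, y)


def planted_table(n=200, n_inform=5, n_noise=30, seed=0, sd=0.3):
    """Each informative feature carries the class signal on its own block
    of samples, so every one of them is needed for full accuracy."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, n)
    blocks = np.arange(n) % max(n_inform, 1)
    cols, names = [], []
    for j in range(n_inform):
        col = np.zeros(n)
        sel = blocks == j
        col[sel] = 1.0 + y[sel] + rng.normal(0, sd, sel.sum())
        cols.append(col)
        names.append(f"inf{j}")
    for j in range(n_noise):
        cols.append(rng.standard_normal(n))
        names.append(f"noise{j}")
    return FeatureTable(names=names, values=np.column_stack(cols),
                        valid_mask=np.ones(n, dtype=bool)), y


class TestSFFS:
    def test_planted_features_recovered(self):
        hits = 0
        seeds = 5
        for seed in range(seeds):
            tbl, y = planted_table(seed=seed)
            sel, _ = sffs_select(tbl, y, k_out=5, seed=seed, folds=2)
            hits += all(f"inf{j}" in sel for j in range(5))
        assert hits >= 0.8 * seeds

    def test_k_equal_to_feature_count_is_identity(self):
        tbl, y = planted_table(n_noise=0, seed=1)
        sel, _ = sffs_select(tbl, y, k_out=5, seed=0, folds=2)
        assert set(sel) == set(tbl.names)

    def test_running_best_score_nondecreasing(self):
        tbl, y = planted_table(n_inform=3, n_noise=8, seed=4)
        _, trace = sffs_select(tbl, y, k_out=6, seed=0, folds=2)
        best = -np.inf
        for _, score in trace:
            assert max(score, best) >= best
            best = max(score, best)

    def test_fewer_survivors_than_k_returns_all(self):
        tbl, y = planted_table(n_inform=2, n_noise=1, seed=5)
        sel, _ = sffs_select(tbl, y, k_out=20, seed=0, folds=2)
        assert set(sel) == set(tbl.names)
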