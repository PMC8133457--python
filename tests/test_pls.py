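import numpy as np
import pytest

import blogmood as bm
from blogmood.pls import Standardizer, _simpls, zscore_fit_apply


class TestZScore:
    def test_simple_column(self):
        Z, center, scale = zscore_fit_apply(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(Z.ravel(), [-1.0, 0.0, 1.0])
        assert center[0] == 4.0 and scale[0] == 2.0

    def test_reapplying_stored_transform_is_idempotent(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((20, 4))
        scaler = Standardizer.fit(M)
        np.testing.assert_allclose(scaler.transform(M), scaler.transform(M))
        np.testing.assert_allclose(
            scaler.inverse_transform(scaler.transform(M)), M, atol=1e-12
        )

    def test_unit_sample_sd(self):
        rng = np.random.default_rng(1)
        Z, _, _ = zscore_fit_apply(rng.standard_normal((15, 3)))
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        M = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            Z, _, _ = zscore_fit_apply(M)
        assert Z.shape == (5, 1)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore_fit_apply(np.ones((5, 2)))


class TestSimplsFit:
    def test_first_direction_proportional_to_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        model = bm.fit_pls(X, y, n_components=1)
        Xz = model.x_scaler.transform(X)
        yz = model.y_scaler.transform(y[:, None])[:, 0]
        cov = Xz.T @ yz
        w = model.x_weights[:, 0]
        cos = abs(w @ cov) / (np.linalg.norm(w) * np.linalg.norm(cov))
        assert cos == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n_targets", [1, 3])
    def test_full_rank_equals_least_squares_oracle(self, n_targets):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, n_targets))
        model = bm.fit_pls(X, Y, n_components=5)
        Xz = model.x_scaler.transform(X)
        Yz = model.y_scaler.transform(Y)
        B_ols, *_ = np.linalg.lstsq(Xz, Yz, rcond=None)
        np.testing.assert_allclose(model.coef, B_ols, atol=1e-8)

    def test_orthogonal_feature_target_recovered_with_one_component(self):
        # with orthogonal predictors the first direction is the target column
        # itself, so one component reproduces a perfectly explainable target;
        # correlated predictors mix into X'y and need further components
        rng = np.random.default_rng(4)
        raw = rng.standard_normal((25, 4))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = Q[:, 2].copy()
        model = bm.fit_pls(Q, y, n_components=1)
        np.testing.assert_allclose(model.predict(Q)[:, 0], y, atol=1e-8)
        # a column of a correlated X is still recovered at full rank
        X = rng.standard_normal((25, 4))
        X[:, 1] += X[:, 2]
        m_full = bm.fit_pls(X, X[:, 2], n_components=4)
        np.testing.assert_allclose(m_full.predict(X)[:, 0], X[:, 2], atol=1e-8)

    def test_matches_reference_pls_implementation(self):
        """Independent cross-check against scikit-learn's PLS regression."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 8))
        y = X @ rng.standard_normal(8) + 0.5 * rng.standard_normal(30)
        ours = bm.fit_pls(X, y, n_components=3)
        ref = PLSRegression(n_components=3, scale=True).fit(X, y)
        np.testing.assert_allclose(
            ours.predict(X).ravel(), ref.predict(X).ravel(), atol=1e-8
        )

    def test_excess_components_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            bm.fit_pls(X, rng.standard_normal(10), n_components=4)

    def test_weight_sign_convention(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 5))
        model = bm.fit_pls(X, rng.standard_normal(20), n_components=2)
        for a in range(2):
            w = model.x_weights[:, a]
            assert w[np.argmax(np.abs(w))] > 0

    def test_scale_equivariance(self):
        """Multiplying a raw feature column by a positive constant leaves
        predictions unchanged."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        X2 = X.copy()
        X2[:, 1] *= 37.0
        m1 = bm.fit_pls(X, y, n_components=2)
        m2 = bm.fit_pls(X2, y, n_components=2)
        np.testing.assert_allclose(m1.predict(X), m2.predict(X2), atol=1e-10)

    def test_training_mse_non_increasing_in_components(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 2))
        mses = []
        for a in range(1, 7):
            m = bm.fit_pls(X, Y, n_components=a)
            resid = m.y_scaler.transform(Y) - m.predict_standardized(X)
            mses.append((resid**2).mean())
        assert all(b <= a + 1e-12 for a, b in zip(mses, mses[1:]))

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 4))
        model = bm.fit_pls(X, rng.standard_normal(20), n_components=2)
        path = tmp_path / "model.json"
        model.save(path)
        back = bm.PLSModel.load(path)
        np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-14)


class TestCVSelection:
    def test_mean_only_mse_near_one_for_standardized_target(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        curve = bm.cv_select_ncomp(X, y, seed=0)
        assert curve.mse_by_ncomp[0] == pytest.approx(1.0, abs=0.25)

    def test_noiseless_single_component_data(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((50, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0, 0.0])
        curve = bm.cv_select_ncomp(X, y, seed=1, max_ncomp=4)
        assert curve.selected_ncomp >= 1
        assert curve.mse_by_ncomp[curve.selected_ncomp] < 0.05
        assert curve.relative_change_pct < -90

    def test_pure_noise_selects_zero_components_mostly(self):
        """Null targets: the stopping rule keeps the mean-only model in the
        majority of runs."""
        rng = np.random.default_rng(13)
        zeros = 0
        n_runs = 100
        for _ in range(n_runs):
            X = rng.standard_normal((40, 8))
            y = rng.standard_normal(40)
            curve = bm.cv_select_ncomp(X, y, seed=int(rng.integers(2**31)))
            zeros += curve.selected_ncomp == 0
        assert zeros > n_runs / 2

    def test_fold_determinism(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        c1 = bm.cv_select_ncomp(X, y, seed=5)
        c2 = bm.cv_select_ncomp(X, y, seed=5)
        np.testing.assert_array_equal(c1.mse_by_ncomp, c2.mse_by_ncomp)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError):
            bm.cv_select_ncomp(rng.standard_normal((4, 3)),
                               rng.standard_normal(4), k_folds=5)


class TestBootstrapFeatureSelection:
    def test_k_equals_p_selects_everything(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        res = bm.bootstrap_select_features(X, y, n_boot=100, k=5, seed=0)
        assert sorted(res.selected) == sorted(res.z_by_feature.index)

    def test_selection_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((30, 6))
        y = X[:, 0] + rng.standard_normal(30)
        a = bm.bootstrap_select_features(X, y, n_boot=300, k=2, seed=9)
        b = bm.bootstrap_select_features(X, y, n_boot=300, k=2, seed=9)
        assert a.selected == b.selected
        np.testing.assert_array_equal(a.z_by_feature, b.z_by_feature)

    def test_planted_features_get_highest_stability(self):
        rng = np.random.default_rng(18)
        n, p = 120, 12
        X = rng.standard_normal((n, p))
        y = X[:, 0] - X[:, 1] + 0.8 * rng.standard_normal(n)
        res = bm.bootstrap_select_features(X, y, n_boot=500, k=2, seed=3)
        assert set(res.selected) == {"x0", "x1"}

    def test_pure_noise_selection_is_unstable(self):
        """Null features: no single feature dominates the selected sets."""
        rng = np.random.default_rng(19)
        X = rng.standard_normal((50, 10))
        from collections import Counter

        counter = Counter()
        n_runs = 40
        for seed in range(n_runs):
            y = rng.standard_normal(50)
            res = bm.bootstrap_select_features(X, y, n_boot=100, k=2, seed=seed)
            counter.update(res.selected)
        assert counter.most_common(1)[0][1] <= n_runs / 2

    def test_too_few_participants_rejected(self):
        rng = np.random.default_rng(20)
        with pytest.raises(ValueError):
            bm.bootstrap_select_features(
                rng.standard_normal((5, 3)), rng.standard_normal(5), n_boot=10
            )


class TestPredictedVsObserved:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((20, 3))
        m = bm.fit_pls(X, X[:, 0], n_components=3)
        res = bm.predicted_vs_observed(m, X, X[:, 0], n_boot=100, seed=0)[0]
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(res.r**2)

    def test_known_population_r_squared(self):
        """beta'x + noise with var split 50/50 gives R^2 near 0.5 at n=1000."""
        rng = np.random.default_rng(22)
        n = 1000
        X = rng.standard_normal((n, 4))
        beta = np.array([1.0, 1.0, 0.0, 0.0])
        y = X @ beta + np.sqrt(2.0) * rng.standard_normal(n)
        m = bm.fit_pls(X, y, n_components=4)
        res = bm.predicted_vs_observed(m, X, y, n_boot=200, seed=1)[0]
        assert res.r_squared == pytest.approx(0.5, abs=0.06)
        assert res.ci_low < res.r < res.ci_high


class TestMultiTarget:
    def test_identical_targets_get_identical_coefficients(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((30, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(30)
        Y = np.column_stack([y, y, y])
        model, _ = bm.fit_multitarget(X, Y, seed=2)
        np.testing.assert_allclose(model.coef[:, 0], model.coef[:, 1], atol=1e-10)
        np.testing.assert_allclose(model.coef[:, 0], model.coef[:, 2], atol=1e-10)

    def test_target_order_equivariance(self):
        rng = np.random.default_rng(24)
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 3))
        m1 = bm.fit_pls(X, Y, n_components=2)
        m2 = bm.fit_pls(X, Y[:, [2, 0, 1]], n_components=2)
        np.testing.assert_allclose(m1.coef[:, [2, 0, 1]], m2.coef, atol=1e-10)

    def test_combined_model_mse_reduction_bounded_by_best_single(self):
        """With shared latent structure the 3-target CV MSE reduction does
        not beat the best single-target reduction."""
        rng = np.random.default_rng(25)
        n = 80
        latent = rng.standard_normal(n)
        X = np.outer(latent, rng.uniform(0.5, 1.0, 6)) + rng.standard_normal((n, 6))
        Y = np.column_stack(
            [latent + s * rng.standard_normal(n) for s in (0.8, 1.0, 1.2)]
        )
        _, combined = bm.fit_multitarget(X, Y, seed=3)
        singles = [
            bm.cv_select_ncomp(X, Y[:, t], seed=3).relative_change_pct
            for t in range(3)
        ]
        assert combined.relative_change_pct >= min(singles) - 5.0
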