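import numpy as np
import pytest
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, r2_score

from reliattn.cohort import CohortSpec, generate_cohort
from reliattn.noise import simulate_correlated_vector
from reliattn.prediction import (
    CVScheme,
    coefficient_hash,
    confound_regress,
    fit_ridge_loo,
    iter_splits,
    loo_ridge_path,
    mae,
    nested_cv_predict,
    pearson_r,
    r_squared,
    ridge_loo_alpha,
    svr_heuristic_c,
)


class TestMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert mae(y, y) == 0.0
        assert pearson_r(y, y + 1) == pytest.approx(1.0)

    def test_mean_prediction_gives_zero_r2(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_r2(self):
        # direct evaluation of the defining sums
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_shifted_prediction(self, rng):
        y = rng.normal(size=30)
        assert mae(y, y + 1) == pytest.approx(1.0)
        assert pearson_r(y, y + 1) == pytest.approx(1.0)

    def test_matches_sklearn(self, rng):
        y, yhat = rng.normal(size=40), rng.normal(size=40)
        assert r_squared(y, yhat) == pytest.approx(r2_score(y, yhat), abs=1e-12)
        assert mae(y, yhat) == pytest.approx(mean_absolute_error(y, yhat), abs=1e-12)

    def test_error_cases(self, rng):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), rng.normal(size=5))
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), rng.normal(size=5))


class TestRidgeLOO:
    def test_single_alpha_grid(self, rng):
        X, y = rng.normal(size=(15, 4)), rng.normal(size=15)
        assert ridge_loo_alpha(X, y, [2.5]) == 2.5

    @pytest.mark.parametrize("shape", [(20, 5), (8, 15)])
    def test_matches_explicit_refits(self, rng, shape):
        # brute-force oracle: n separate Ridge fits per alpha
        n, p = shape
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        alphas = np.logspace(-2, 3, 7)
        shortcut = loo_ridge_path(X, y, alphas)
        brute = []
        for a in alphas:
            errs = []
            for i in range(n):
                m = np.ones(n, bool)
                m[i] = False
                model = Ridge(alpha=a).fit(X[m], y[m])
                errs.append((y[i] - model.predict(X[i : i + 1])[0]) ** 2)
            brute.append(np.mean(errs))
        np.testing.assert_allclose(shortcut, brute, rtol=1e-8)
        assert ridge_loo_alpha(X, y, alphas) == alphas[int(np.argmin(brute))]

    def test_fitted_model_matches_sklearn(self, rng):
        X = rng.normal(size=(30, 6))
        y = X[:, 0] + rng.normal(size=30)
        model = fit_ridge_loo(X, y)
        ref = Ridge(alpha=model.alpha_).fit(X, y)
        np.testing.assert_allclose(model.coef_, ref.coef_, atol=1e-8)
        assert model.intercept_ == pytest.approx(ref.intercept_, abs=1e-8)

    def test_pure_noise_selects_heavy_shrinkage(self):
        # under zero signal the LOO criterion drives alpha far up the grid,
        # while a strong signal keeps it small
        grid = np.logspace(-3, 5, 17)
        rng = np.random.default_rng(314)
        noise_alphas = [
            ridge_loo_alpha(rng.normal(size=(200, 10)), rng.normal(size=200), grid)
            for _ in range(100)
        ]
        assert np.mean(np.asarray(noise_alphas) >= 1e2) >= 0.90
        signal_alphas = []
        for _ in range(50):
            X = rng.normal(size=(200, 10))
            y = X[:, 0] + 0.3 * rng.normal(size=200)
            signal_alphas.append(ridge_loo_alpha(X, y, grid))
        assert np.median(signal_alphas) < np.median(noise_alphas)

    def test_degenerate_features_rejected(self, rng):
        with pytest.raises(ValueError, match="variance|degenerate"):
            fit_ridge_loo(np.ones((10, 3)), rng.normal(size=10))


class TestConfoundRegress:
    def test_orthogonal_confound_leaves_features(self, rng):
        n = 200
        C = rng.normal(size=(n, 1))
        X = rng.normal(size=(n, 3))
        X -= np.column_stack([np.ones(n), C]) @ np.linalg.lstsq(
            np.column_stack([np.ones(n), C]), X, rcond=None
        )[0]
        X += 5.0  # re-add a mean; intercept absorbs it
        Xtr, Xte = confound_regress(X, X, C, C)
        np.testing.assert_allclose(Xtr + 5.0, X, atol=1e-9)

    def test_feature_equal_to_confound_residualises_to_zero(self, rng):
        C = rng.normal(size=(50, 1))
        Xtr, _ = confound_regress(C.copy(), C.copy(), C, C)
        np.testing.assert_allclose(Xtr, 0.0, atol=1e-10)

    def test_train_betas_applied_to_test(self, rng):
        Ctr, Cte = rng.normal(size=(60, 2)), rng.normal(size=(20, 2))
        Xtr = Ctr @ rng.normal(size=(2, 4)) + rng.normal(size=(60, 4))
        Xte = Cte @ rng.normal(size=(2, 4)) + rng.normal(size=(20, 4))
        Rtr, Rte = confound_regress(Xtr, Xte, Ctr, Cte)
        # train residuals orthogonal to confounds
        D = np.column_stack([np.ones(60), Ctr])
        np.testing.assert_allclose(D.T @ Rtr, 0.0, atol=1e-8)
        # test residuals reproduce the normal-equations solution exactly
        Dte = np.column_stack([np.ones(20), Cte])
        beta = np.linalg.solve(D.T @ D, D.T @ Xtr)
        np.testing.assert_allclose(Rte, Xte - Dte @ beta, atol=1e-9)

    def test_rank_deficient_rejected(self, rng):
        C = rng.normal(size=(30, 1))
        with pytest.raises(ValueError, match="rank"):
            confound_regress(
                rng.normal(size=(30, 2)),
                rng.normal(size=(10, 2)),
                np.hstack([C, C]),
                rng.normal(size=(10, 2)),
            )


class TestSVRHeuristic:
    def test_known_row_norms(self):
        X = np.full((3, 4), 1.0)  # squared row norm 4
        assert svr_heuristic_c(X) == pytest.approx(0.5)
        assert svr_heuristic_c(np.eye(5)) == pytest.approx(1.0)

    def test_matches_gram_diagonal(self, rng):
        X = rng.normal(size=(10, 6))
        G = X @ X.T
        expected = 1.0 / np.mean(np.sqrt(np.diag(G)))
        assert svr_heuristic_c(X) == pytest.approx(expected, abs=1e-12)

    def test_zero_row_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        X[2] = 0.0
        with pytest.raises(ValueError, match="zero"):
            svr_heuristic_c(X)


class TestCVSchemes:
    def test_repeated_kfold_shape(self):
        splits = list(iter_splits(CVScheme(outer_folds=5, repeats=3, seed=1), 50))
        assert len(splits) == 15
        for tr, te in splits:
            assert len(np.intersect1d(tr, te)) == 0
            assert len(tr) + len(te) == 50

    def test_family_scheme_never_splits_a_family(self, rng):
        fams = np.repeat([f"f{i}" for i in range(20)], 5)
        scheme = CVScheme(kind="grouped_family", repeats=5, test_family_fraction=0.3, seed=2)
        for tr, te in iter_splits(scheme, 100, fams):
            assert set(fams[tr]).isdisjoint(set(fams[te]))
            assert len(set(fams[te])) == 6  # ceil(0.3 * 20)

    def test_family_scheme_requires_ids(self):
        with pytest.raises(ValueError, match="family"):
            list(iter_splits(CVScheme(kind="grouped_family"), 10, None))


class TestNestedCV:
    def test_realizable_linear_signal(self, rng):
        n = 300
        X = rng.normal(size=(n, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 1.5, -1.0])
        res = nested_cv_predict(X, y, CVScheme(seed=0, repeats=1), row_zscore=False)
        assert res.r2_mean >= 0.95

    def test_null_target_r2_nonpositive_on_average(self):
        # CV R^2 of pure noise is <= 0 in expectation
        rng = np.random.default_rng(99)
        means = []
        for _ in range(100):
            X = rng.normal(size=(300, 20))
            y = rng.normal(size=300)
            res = nested_cv_predict(
                X, y, CVScheme(seed=1, repeats=1), row_zscore=False
            )
            means.append(res.r2_mean)
        assert np.mean(means) <= 0.02

    def test_cohort_effect_r2_recovery(self):
        # population R^2 of the best read-out is effect_r^2; averaged over
        # three cohorts to tame cohort-level Monte-Carlo noise
        vals = []
        for seed in (5, 6, 7):
            spec = CohortSpec(
                n_participants=2000, n_parcels=21, effect_r=0.5, target_icc=1.0, seed=seed
            )
            cohort = generate_cohort(spec)
            res = nested_cv_predict(
                cohort.features, cohort.target, CVScheme(seed=seed, repeats=2)
            )
            vals.append(res.r2_mean)
        assert np.mean(vals) == pytest.approx(0.25, abs=0.05)

    def test_effect_recovery_across_effect_sizes(self):
        # out-of-sample pearson of the pipeline on the clean latent trait
        for effect_r in (0.3, 0.5, 0.7):
            spec = CohortSpec(
                n_participants=2000, n_parcels=21, effect_r=effect_r, target_icc=1.0, seed=6
            )
            cohort = generate_cohort(spec)
            res = nested_cv_predict(
                cohort.features, cohort.latent_trait, CVScheme(seed=6, repeats=1)
            )
            assert res.pearson_mean == pytest.approx(effect_r, abs=0.07)

    def test_spearman_attenuation_recovery(self):
        # observed pearson ~ effect_r * sqrt(ICC) (Spearman, 1910)
        for icc in (0.81, 0.49):
            spec = CohortSpec(
                n_participants=2000, n_parcels=21, effect_r=0.7, target_icc=icc, seed=9
            )
            cohort = generate_cohort(spec)
            res = nested_cv_predict(
                cohort.features, cohort.target, CVScheme(seed=9, repeats=1)
            )
            assert res.pearson_mean == pytest.approx(0.7 * np.sqrt(icc), abs=0.07)

    def test_leakage_guard_test_targets_do_not_touch_training(self, rng):
        # permuting test-fold targets never changes the training-fold fit
        n = 120
        X = rng.normal(size=(n, 10))
        y = X[:, 0] + rng.normal(size=n)
        scheme = CVScheme(outer_folds=4, repeats=1, seed=3)
        splits = list(iter_splits(scheme, n))
        tr, te = splits[0]
        from reliattn.prediction import _zscore_cols_train_test

        Xtr, _ = _zscore_cols_train_test(X[tr], X[te])
        h1 = coefficient_hash(fit_ridge_loo(Xtr, y[tr]))
        y2 = y.copy()
        y2[te] = rng.permutation(y2[te])
        h2 = coefficient_hash(fit_ridge_loo(Xtr, y2[tr]))
        assert h1 == h2

    def test_attenuation_identity_for_trained_model(self, rng):
        # corr(yhat, surrogate) = rho * corr(yhat, clean) for the model's
        # fixed held-out predictions
        from reliattn.noise import PhenotypeVector

        n = 200
        X = rng.normal(size=(n, 10))
        y = X[:, 0] + rng.normal(size=n)
        model = fit_ridge_loo(X[:150], y[:150])
        yhat = model.predict(X[150:])
        clean = PhenotypeVector(np.arange(50), y[150:])
        for rho in (0.9, 0.5):
            # a trained model's predictions are not a function of the clean
            # target alone, so the identity holds over surrogate draws
            cors = [
                pearson_r(yhat, simulate_correlated_vector(clean, rho, rng).scores)
                for _ in range(300)
            ]
            rhs = rho * pearson_r(yhat, clean.scores)
            assert np.mean(cors) == pytest.approx(rhs, abs=0.02)

    def test_family_scheme_via_cohort(self):
        spec = CohortSpec(n_participants=300, n_parcels=10, mean_family_size=2.0, seed=4)
        cohort = generate_cohort(spec)
        scheme = CVScheme(kind="grouped_family", repeats=3, seed=4)
        res = nested_cv_predict(
            cohort.features, cohort.target, scheme, family_ids=cohort.family_ids
        )
        assert len(res.r2_per_fold) == 3

    def test_svr_control_path(self, rng):
        n = 120
        X = rng.normal(size=(n, 8))
        y = X[:, 0] * 2 + rng.normal(size=n) * 0.1
        res = nested_cv_predict(
            X, y, CVScheme(outer_folds=5, repeats=1, seed=0), algorithm="svr",
            row_zscore=False,
        )
        assert res.r2_mean > 0.8

    def test_misaligned_ids_rejected(self):
        spec = CohortSpec(n_participants=30, n_parcels=4, seed=1)
        cohort = generate_cohort(spec)
        bad = simulate_correlated_vector(
            cohort.target, 0.9, np.random.default_rng(0)
        ).as_phenotype()
        bad.participant_ids = bad.participant_ids[::-1].copy()
        with pytest.raises(ValueError, match="aligned"):
            nested_cv_predict(cohort.features, bad, CVScheme(seed=0))
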