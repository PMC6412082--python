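"""Kernel construction, GPR against closed-form oracles, CV and permutations."""

import numpy as np
import pytest

from brainpad import (
    FeatureVector,
    GPRHyperparams,
    brain_pad,
    build_cross_kernel,
    build_kernel,
    crossvalidate,
    cv_metrics,
    fit_gpr,
    load_model,
    permutation_test,
    predict_gpr,
    predict_mean,
    save_model,
)
from brainpad.model import AgeBiasCorrection, assign_folds, center_gram
from brainpad.volumes import DimensionError


def feats_from(X, mask_id="m"):
    return [FeatureVector(values=x, mask_id=mask_id, subject_id=f"s{i}")
            for i, x in enumerate(X)]


class TestKernel:
    def test_orthonormal_features_give_identity(self):
        K = build_kernel(feats_from(np.eye(2)), scale_mode="none")
        np.testing.assert_allclose(K.matrix, np.eye(2), atol=1e-15)

    @pytest.mark.parametrize("scale_mode", ["none", "by_voxel_count", "trace_normalized"])
    def test_matches_brute_force_double_loop(self, rng, scale_mode):
        X = rng.normal(size=(6, 9))
        K = build_kernel(feats_from(X), scale_mode=scale_mode)
        brute = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                brute[i, j] = float(np.dot(X[i], X[j]))
        if scale_mode == "by_voxel_count":
            brute /= 9
        elif scale_mode == "trace_normalized":
            brute *= 6 / np.trace(brute)
        assert np.abs(K.matrix - brute).max() <= 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_symmetric_and_psd_on_random_features(self, seed):
        g = np.random.default_rng(seed)
        X = g.normal(size=(g.integers(3, 12), g.integers(2, 30)))
        K = build_kernel(feats_from(X))
        assert np.abs(K.matrix - K.matrix.T).max() <= 1e-12
        assert K.min_eigenvalue() >= -1e-8 * np.trace(K.matrix) / K.n

    def test_duplicated_subject_duplicates_row_and_stays_psd(self, rng):
        X = rng.normal(size=(4, 6))
        Xdup = np.vstack([X, X[1]])
        K = build_kernel(feats_from(Xdup))
        np.testing.assert_allclose(K.matrix[4], K.matrix[1], rtol=1e-12)
        assert K.min_eigenvalue() >= -1e-8 * np.trace(K.matrix) / K.n

    def test_too_few_subjects_and_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            build_kernel(feats_from(rng.normal(size=(1, 4))))
        bad = [FeatureVector(np.ones(3), "m"), FeatureVector(np.ones(4), "m")]
        with pytest.raises(DimensionError):
            build_kernel(bad)


class TestCrossKernel:
    def test_test_set_equal_to_train_set_reproduces_gram(self, rng):
        f = feats_from(rng.normal(size=(5, 7)))
        K = build_kernel(f)
        C = build_cross_kernel(f, f, scale_mode=K.scale_mode)
        np.testing.assert_allclose(C, K.matrix, atol=1e-12)

    def test_zero_test_vector_gives_zero_row(self, rng):
        train = feats_from(rng.normal(size=(4, 5)))
        zero = [FeatureVector(np.zeros(5), "m")]
        C = build_cross_kernel(zero, train)
        np.testing.assert_array_equal(C, np.zeros((1, 4)))

    def test_matches_brute_force(self, rng):
        Xte, Xtr = rng.normal(size=(3, 8)), rng.normal(size=(5, 8))
        C = build_cross_kernel(feats_from(Xte), feats_from(Xtr))
        brute = np.array([[x @ t for t in Xtr] for x in Xte]) / 8
        assert np.abs(C - brute).max() <= 1e-10

    def test_mask_mismatch_rejected(self, rng):
        tr = feats_from(rng.normal(size=(3, 4)), mask_id="a")
        te = feats_from(rng.normal(size=(2, 4)), mask_id="b")
        with pytest.raises(ValueError, match="mask"):
            build_cross_kernel(te, tr)


class TestGPR:
    def test_identity_kernel_interpolates_in_small_noise_limit(self, rng):
        y = rng.normal(30, 5, size=6)
        model = fit_gpr(np.eye(6), y, hyper=GPRHyperparams(1.0, 1e-12, 0.0),
                        center=False)
        pred = predict_mean(model, np.eye(6))
        np.testing.assert_allclose(pred, y, atol=1e-6)

    def test_predictive_mean_equals_kernel_ridge_closed_form(self):
        # the module's primary oracle: mu + k*'(sK + sn2 I)^-1 (y - mu)
        for seed in range(20):
            g = np.random.default_rng(seed)
            n = int(g.integers(5, 31))
            X = g.normal(size=(n, int(g.integers(3, 20))))
            y = g.normal(40, 10, size=n)
            s, sn2 = float(g.uniform(0.2, 3)), float(g.uniform(0.1, 5))
            K = build_kernel(feats_from(X))
            model = fit_gpr(K, y, hyper=GPRHyperparams(s, sn2, 0.0), center=False)
            Xte = g.normal(size=(4, X.shape[1]))
            C = build_cross_kernel(feats_from(Xte), feats_from(X))
            mu = y.mean()
            closed = mu + s * C @ np.linalg.solve(s * K.matrix + sn2 * np.eye(n), y - mu)
            assert np.abs(predict_mean(model, C) - closed).max() <= 1e-8

    def test_centered_fit_equals_closed_form_on_centered_matrices(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(40, 10, size=12)
        s, sn2 = 0.7, 1.3
        K = build_kernel(feats_from(X))
        model = fit_gpr(K, y, hyper=GPRHyperparams(s, sn2, 0.0), center=True)
        Xc = X - X.mean(axis=0)
        Kc, _, _ = center_gram(K.matrix)
        np.testing.assert_allclose(Kc, (Xc @ Xc.T) / X.shape[1], atol=1e-12)
        Xte = rng.normal(size=(3, 6))
        C = build_cross_kernel(feats_from(Xte), feats_from(X))
        Cc = ((Xte - X.mean(axis=0)) @ Xc.T) / X.shape[1]
        mu = y.mean()
        closed = mu + s * Cc @ np.linalg.solve(s * Kc + sn2 * np.eye(12), y - mu)
        np.testing.assert_allclose(predict_mean(model, C), closed, atol=1e-8)

    def test_constant_ages_predict_that_age(self, rng):
        X = rng.normal(size=(8, 5))
        K = build_kernel(feats_from(X))
        model = fit_gpr(K, np.full(8, 33.0), hyper="optimize")
        C = build_cross_kernel(feats_from(rng.normal(size=(3, 5))), feats_from(X))
        np.testing.assert_allclose(predict_mean(model, C), 33.0, atol=1e-8)

    def test_zero_cross_row_reverts_to_prior_mean_uncentered(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(30, 5, size=6)
        model = fit_gpr(build_kernel(feats_from(X)), y,
                        hyper=GPRHyperparams(1.0, 0.5, 0.0), center=False)
        pred = predict_mean(model, np.zeros((1, 6)))
        assert pred[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_adding_constant_to_ages_shifts_predictions_by_it(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.uniform(20, 50, size=20)
        K = build_kernel(feats_from(X))
        C = build_cross_kernel(feats_from(rng.normal(size=(5, 10))), feats_from(X))
        p0 = predict_mean(fit_gpr(K, y), C)
        p9 = predict_mean(fit_gpr(K, y + 9.0), C)
        np.testing.assert_allclose(p9, p0 + 9.0, atol=1e-6)

    def test_feature_scaling_leaves_optimized_predictions_unchanged(self, rng):
        X = rng.normal(size=(25, 12))
        y = X[:, 0] * 5 + 35 + rng.normal(0, 0.5, 25)
        Xte = rng.normal(size=(4, 12))
        preds = []
        for c in (1.0, 10.0):
            K = build_kernel(feats_from(c * X))
            C = build_cross_kernel(feats_from(c * Xte), feats_from(c * X))
            preds.append(predict_mean(fit_gpr(K, y, hyper="optimize"), C))
        np.testing.assert_allclose(preds[0], preds[1], rtol=1e-4, atol=1e-4)

    def test_non_psd_kernel_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            fit_gpr(bad, np.array([1.0, 2.0]), hyper=GPRHyperparams(1, 1, 0),
                    center=False)

    def test_save_load_roundtrip_bit_exact(self, tmp_path, rng):
        X = rng.normal(size=(10, 6))
        y = rng.uniform(20, 60, 10)
        model = fit_gpr(build_kernel(feats_from(X)), y)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.alpha, model.alpha)
        assert back.hyper == model.hyper
        assert back.subject_ids == model.subject_ids
        C = build_cross_kernel(feats_from(rng.normal(size=(3, 6))), feats_from(X))
        np.testing.assert_array_equal(predict_mean(back, C), predict_mean(model, C))


class TestBrainPAD:
    def test_identity_predicted_minus_chronological(self):
        assert brain_pad(37.36, 24.49) == pytest.approx(12.87, abs=1e-12)

    def test_prediction_records_carry_brain_pad(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.uniform(20, 30, 6)
        model = fit_gpr(build_kernel(feats_from(X)), y)
        C = build_cross_kernel(feats_from(X[:2]), feats_from(X))
        recs = predict_gpr(model, C, subject_ids=["a", "b"], chronological_ages=y[:2])
        for r in recs:
            assert r.brain_pad == r.predicted_age - r.chronological_age

    def test_bias_correction_inverts_linear_attenuation(self, rng):
        ages = rng.uniform(20, 60, 200)
        attenuated = 0.9 * ages + 4.0 + rng.normal(0, 0.01, 200)
        corr = AgeBiasCorrection.fit(attenuated, ages)
        np.testing.assert_allclose(corr.apply(attenuated), ages, atol=0.1)


class TestCrossValidation:
    def test_metrics_on_toy_residuals(self):
        ages = np.array([10.0, 20.0, 30.0])
        pred = ages + np.array([1.0, -2.0, 2.0])
        _, _, mae, rmse = cv_metrics(pred, ages)
        assert mae == pytest.approx(5.0 / 3.0)
        assert rmse == pytest.approx(np.sqrt(3.0))
        r, r2, mae, rmse = cv_metrics(ages, ages)
        assert (r, r2, mae, rmse) == (1.0, 1.0, 0.0, 0.0)

    def test_folds_near_equal_and_each_subject_once(self, rng):
        folds = assign_folds(23, 10, rng)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 1 and sizes.sum() == 23

    def test_fewer_subjects_than_folds_reduces_with_warning(self, make_features):
        feats = make_features(8, 5)
        ages = np.linspace(20, 50, 8)
        with pytest.warns(UserWarning, match="reducing folds"):
            cv = crossvalidate(feats, ages, seed=0, n_folds=10,
                               hyper=GPRHyperparams(1, 1, 0))
        assert len(np.unique(cv.fold_assignment)) == 8

    def test_strong_linear_signal_recovers_age(self, rng):
        n, d = 80, 30
        ages = rng.uniform(19, 56, n)
        m = rng.normal(size=d)
        X = np.outer(ages, m) + rng.normal(0, 0.5, size=(n, d))
        cv = crossvalidate(feats_from(X), ages, seed=1)
        assert cv.r > 0.95
        assert cv.rmse >= cv.mae

    def test_cv_deterministic_for_fixed_seed(self, make_features):
        feats = make_features(20, 10)
        ages = np.linspace(20, 50, 20)
        a = crossvalidate(feats, ages, seed=5)
        b = crossvalidate(feats, ages, seed=5)
        np.testing.assert_array_equal(a.predicted_age, b.predicted_age)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)


class TestPermutation:
    def test_perfect_signal_attains_minimum_p(self, rng):
        ages = rng.uniform(19, 56, 30)
        X = np.outer(ages, np.ones(3)) + rng.normal(0, 1e-3, size=(30, 3))
        res = permutation_test(feats_from(X), ages, n_perm=99, seed=0)
        assert res.p == pytest.approx(1.0 / 100.0)

    def test_observed_r_below_all_permutations_gives_p_one(self):
        # uninformative (all-zero) features make every out-of-fold prediction
        # the other fold's training mean; assigning the large ages to one of
        # two folds then makes the observed predictions maximally
        # anti-correlated with age, so no permutation scores lower
        seed, n = 0, 12
        rng_folds = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
        folds = assign_folds(n, 2, rng_folds)
        ages = np.where(folds == 0, 20.0, 50.0) + np.arange(n) * 1e-3
        X = np.zeros((n, 4))
        res = permutation_test(feats_from(X), ages, n_perm=49, seed=seed,
                               n_folds=2, hyper=GPRHyperparams(1.0, 1.0, 0.0))
        assert res.r_observed < -0.99
        assert res.r_observed <= res.null_r.min()
        assert res.p == 1.0

    def test_p_bounds_and_smoothing(self, make_features):
        feats = make_features(12, 6)
        res = permutation_test(feats, np.linspace(20, 40, 12), n_perm=19, seed=2,
                               hyper=GPRHyperparams(1, 1, 0))
        assert 1.0 / 20.0 <= res.p <= 1.0

    def test_n_perm_must_be_positive(self, make_features):
        with pytest.raises(ValueError):
            permutation_test(make_features(5, 3), np.arange(5.0), n_perm=0)
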