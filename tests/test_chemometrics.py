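"""NIPALS PCA/PLS engine against independent oracles (SVD, OLS, brute-force
CV, scikit-learn, the F-quantile formula)."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import honeyscreen as hs
from honeyscreen.chemometrics import (
    LatentModel,
    cross_validate,
    fit_pca,
    fit_pls,
    fit_plsda,
    fit_scaling,
    hotelling_limit,
    hotelling_t2,
    predict_y,
    project_scores,
)
from honeyscreen.preprocess import assemble_matrix


class TestScaling:
    def test_uv_hand_values(self):
        state = fit_scaling(np.array([[1.0], [3.0]]), "uv")
        assert state.means[0] == pytest.approx(2.0)
        assert state.scales[0] == pytest.approx(np.sqrt(2.0))

    def test_constant_column_flagged_and_inert(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        state = fit_scaling(X, "uv")
        assert state.zero_variance[0] and not state.zero_variance[1]
        assert np.allclose(state.transform(X)[:, 0], 0.0)

    def test_transform_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4)) * 3 + 1
        state = fit_scaling(X, "uv")
        assert np.allclose(state.inverse(state.transform(X)), X, atol=1e-12)


class TestPCA:
    @pytest.mark.parametrize("shape", [(8, 5), (20, 50), (15, 7)])
    def test_nipals_matches_svd(self, shape):
        rng = np.random.default_rng(42)
        X = rng.normal(size=shape)
        A = min(4, shape[0] - 1, shape[1])
        model = fit_pca(X, A)
        Xc = X - X.mean(axis=0)
        _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(A):
            v = Vt[a]
            v = v * np.sign(v[np.argmax(np.abs(v))])
            assert np.max(np.abs(model.P[:, a] - v)) < 1e-8
            assert np.allclose(model.T[:, a] ** 2, (Xc @ v) ** 2, atol=1e-8)

    def test_rank_one_explains_everything(self):
        u = np.arange(1.0, 7.0)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        model = fit_pca(u @ v, 1)
        assert model.diagnostics["r2x_per_component"][0] == pytest.approx(1.0)

    def test_duplicated_row_same_score(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        X[3] = X[0]
        model = fit_pca(X, 2)
        assert np.allclose(model.T[0], model.T[3], atol=1e-10)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).normal(size=(4, 3)), 5)


class TestPLS:
    def test_identity_regression(self):
        y = np.arange(1.0, 9.0)
        model = fit_pls(y[:, None], y, A=1, scaling="center")
        assert model.diagnostics["R2Y"] == pytest.approx(1.0)
        assert np.allclose(predict_y(model, y[:, None]), y, atol=1e-10)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = fit_pls(X, y, A=4, scaling="center")
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.max(np.abs(model.B - b_ols)) < 1e-8

    def test_matches_sklearn_predictions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 8))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(size=20) * 0.1
        for a in (1, 2, 3):
            ours = predict_y(fit_pls(X, y, A=a, scaling="center"), X)
            sk = PLSRegression(n_components=a, scale=False).fit(X, y).predict(X).ravel()
            assert np.max(np.abs(ours - sk)) < 1e-8

    def test_permuted_response_has_no_predictive_power(self):
        """Median Q2 over 50 shuffled-y datasets is <= 0."""
        rng = np.random.default_rng(5)
        q2 = []
        for _ in range(50):
            X = rng.normal(size=(20, 5))
            y = rng.permutation(np.linspace(0, 1, 20))
            cv = cross_validate(X, y, A_max=2, scheme="venetian", scaling="center")
            q2.append(cv.q2.max())
        assert np.median(q2) <= 0.0

    def test_degenerate_response_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(8), A=1)

    def test_weights_unit_norm_scores_orthogonal(self, models):
        for model in (models.plsda_I, models.plsda_II, models.pls_III, models.pls_IV):
            norms = np.linalg.norm(model.W, axis=0)
            assert np.allclose(norms, 1.0, atol=1e-10)
            G = model.T.T @ model.T
            off = G - np.diag(np.diag(G))
            assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))


class TestPLSDA:
    def test_separated_clusters_recover_class_codes(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, (10, 6)), rng.normal(10, 1, (10, 6))])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_plsda(X, labels, A=2, scaling="uv", positive="b")
        fitted = predict_y(model, X)
        assert np.max(np.abs(fitted - (labels == "b"))) < 0.1

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(14, 5))
        labels = np.array(["a"] * 7 + ["b"] * 7)
        ya = predict_y(fit_plsda(X, labels, A=2, positive="b"), X)
        yb = predict_y(fit_plsda(X, labels, A=2, positive="a"), X)
        assert np.allclose(ya, 1.0 - yb, atol=1e-10)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError):
            fit_plsda(X, ["a"] * 6, A=1)

    def test_training_classes_separate(self, models, training):
        """Stage-1 PLS-DA separates N from adulterated on its training set."""
        _, matrix, labels = training
        fitted = predict_y(models.plsda_I, matrix.values)
        n_vals = fitted[np.array(labels) == "N"]
        a_vals = fitted[np.array(labels) != "N"]
        assert n_vals.max() < a_vals.min()


class TestProjection:
    def test_training_rows_reproject_onto_training_scores(self, models, training):
        _, matrix, labels = training
        model = models.plsda_I
        T_new = project_scores(model, matrix.values)
        assert np.allclose(T_new, model.T, atol=1e-10 * np.abs(model.T).max())

    def test_mean_spectrum_projects_to_origin(self, models):
        model = models.plsda_I
        mean_row = model.scaling.inverse(np.zeros((1, model.P.shape[0])))
        assert np.allclose(project_scores(model, mean_row), 0.0, atol=1e-10)

    def test_projection_matches_sequential_deflation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 9))
        y = X[:, 1] + rng.normal(size=15) * 0.3
        model = fit_pls(X, y, A=3, scaling="center")
        Xnew = rng.normal(size=(4, 9))
        Z = model.scaling.transform(Xnew)
        # brute force: deflate component by component
        T_seq = np.zeros((4, 3))
        Zd = Z.copy()
        for a in range(3):
            t = Zd @ model.W[:, a]
            T_seq[:, a] = t
            Zd = Zd - np.outer(t, model.P[:, a])
        assert np.allclose(project_scores(model, Xnew), T_seq, atol=1e-10)

    def test_dimension_mismatch(self, models):
        with pytest.raises(ValueError):
            project_scores(models.plsda_I, np.zeros((1, 5)))


class TestCrossValidation:
    def test_noiseless_linear_rmsecv_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(14, 1))
        y = 2.0 * x[:, 0]
        cv = cross_validate(x, y, A_max=1, scheme="venetian", scaling="center")
        assert cv.rmsecv[0] < 1e-8
        assert cv.chosen_A == 1

    def test_matches_brute_force_loo(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 5))
        y = X[:, 0] * 2 + rng.normal(size=12) * 0.1
        cv = cross_validate(X, y, A_max=3, scheme="loo", scaling="center")
        press = np.zeros(3)
        for i in range(12):
            tr = np.setdiff1d(np.arange(12), [i])
            for a in range(1, 4):
                m = fit_pls(X[tr], y[tr], A=a, scaling="center")
                press[a - 1] += (y[i] - predict_y(m, X[i : i + 1])[0]) ** 2
        assert np.allclose(cv.rmsecv, np.sqrt(press / 12), atol=1e-10)

    def test_chosen_A_is_argmin_with_small_tie(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(21, 6))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=21) * 0.05
        cv = cross_validate(X, y, A_max=4, scheme="venetian", scaling="center")
        assert cv.chosen_A == int(np.argmin(cv.rmsecv)) + 1

    def test_too_few_samples_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            cross_validate(X, np.arange(5.0), A_max=2, n_folds=7)


class TestHotelling:
    def test_limit_monotone_in_confidence(self):
        limits = [hotelling_limit(24, 3, alpha) for alpha in (0.10, 0.05, 0.01)]
        assert limits[0] < limits[1] < limits[2]

    def test_frozen_f_table_value(self):
        # A(n-1)(n+1)/(n(n-A)) * F_{0.95}(A, n-A) for n=24, A=2
        assert hotelling_limit(24, 2, 0.05) == pytest.approx(7.4997354, rel=1e-6)

    def test_single_component_reduces_to_f1(self):
        n = 24
        from scipy.stats import f as f_dist

        expected = (n - 1) * (n + 1) / (n * (n - 1)) * f_dist.ppf(0.95, 1, n - 1)
        assert hotelling_limit(n, 1, 0.05) == pytest.approx(expected, rel=1e-12)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            hotelling_limit(3, 3)

    def test_training_t2_mostly_inside_limit(self, models):
        model = models.plsda_II
        X = model.scaling.inverse(np.zeros((1, model.P.shape[0])))
        t2 = hotelling_t2(model, X)
        assert t2[0] < hotelling_limit(24, model.A)  # the mean is central


class TestStatisticalProperties:
    def test_q2_below_r2y(self):
        """Cross-validated fit never beats the training fit (50 datasets)."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            X = rng.normal(size=(16, 6))
            y = X @ rng.normal(size=6) + rng.normal(size=16) * 0.5
            a = int(rng.integers(1, 4))
            model = fit_pls(X, y, A=a, scaling="center")
            cv = cross_validate(X, y, A_max=a, scheme="venetian", scaling="center")
            assert cv.q2[a - 1] <= model.diagnostics["R2Y"] + 1e-10

    def test_concentration_recovery_bias(self, acq):
        """PLS on synthetic calibration recovers >=2 mg/mL truths within 5%."""
        errs = []
        for seed in range(20):
            cal = hs.make_calibration_set(
                "tadalafil", levels=(0.5, 1.0, 2.0, 4.0, 8.0), replicates=2,
                acq=acq, seed=100 + seed,
            )
            M = assemble_matrix([s for s, _ in cal])
            conc = np.array([c for _, c in cal])
            cols = M.region_columns(5.6, 6.4)
            model = fit_pls(M.values[:, cols], conc, A=2, scaling="center")
            fitted = predict_y(model, M.values[:, cols])
            sel = conc >= 2.0
            errs.append(np.mean((fitted[sel] - conc[sel]) / conc[sel]))
        assert abs(np.mean(errs)) < 0.05

    def test_model_serialization_round_trip(self, models):
        d = models.plsda_I.to_dict()
        back = LatentModel.from_dict(d)
        rng = np.random.default_rng(13)
        X = rng.normal(size=(3, models.plsda_I.P.shape[0]))
        assert np.allclose(predict_y(models.plsda_I, X), predict_y(back, X))
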