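import numpy as np
import pytest

from fixir.plsr import (
    EvalReport,
    FeatureMatrix,
    PLSRModel,
    coefficient_spectrum,
    evaluate,
    fit_plsr,
    predict,
    select_components,
    split_holdout,
)


def make_fm(X, y, groups=None):
    return FeatureMatrix(X, y, [f"s{i}" for i in range(len(y))], groups=groups)


def svd_pls_oracle(X, y, k):
    """Independent PLS1 oracle: weights from the SVD of the X'y covariance
    at each deflation step; prediction by sequential score projection
    (never through an assembled coefficient vector)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    Xd, yd = Xc.copy(), yc.copy()
    Ws, Ps, Qs = [], [], []
    for _ in range(k):
        cov = (Xd.T @ yd).reshape(-1, 1)
        u, _, _ = np.linalg.svd(cov, full_matrices=False)
        w = u[:, 0]
        s = Xd @ w
        ss = s @ s
        p = Xd.T @ s / ss
        q = yd @ s / ss
        Xd = Xd - np.outer(s, p)
        yd = yd - q * s
        Ws.append(w)
        Ps.append(p)
        Qs.append(q)

    def pred(rows):
        rows = np.atleast_2d(rows) - X.mean(axis=0)
        out = np.full(rows.shape[0], y.mean())
        r = rows.copy()
        for w, p, q in zip(Ws, Ps, Qs):
            t = r @ w
            out += q * t
            r = r - np.outer(t, p)
        return out

    return pred


class TestSplitHoldout:
    def _study_matrix(self, n_per=30, times=(0, 1, 2, 4, 6, 12, 24)):
        rng = np.random.default_rng(1)
        y = np.repeat(times, n_per).astype(float)
        X = rng.normal(size=(len(y), 5))
        groups = [f"g{i // 2}" for i in range(len(y))]
        return make_fm(X, y, groups)

    def test_printed_210_row_design(self):
        fm = self._study_matrix()
        train, val = split_holdout(fm, 0.25, seed=3)
        assert val.n == 52
        assert train.n == 158

    def test_every_stratum_in_validation(self):
        fm = self._study_matrix()
        _, val = split_holdout(fm, 0.25, seed=3)
        assert set(val.y) == {0, 1, 2, 4, 6, 12, 24}

    def test_half_split_of_four(self):
        fm = make_fm(np.arange(8).reshape(4, 2).astype(float), np.full(4, 2.0))
        train, val = split_holdout(fm, 0.5, seed=0)
        assert (train.n, val.n) == (2, 2)

    def test_disjoint_exhaustive(self):
        fm = self._study_matrix()
        train, val = split_holdout(fm, 0.25, seed=9)
        assert sorted(train.row_ids + val.row_ids) == sorted(fm.row_ids)
        assert not set(train.row_ids) & set(val.row_ids)

    def test_seed_reproducible(self):
        fm = self._study_matrix()
        a = split_holdout(fm, 0.25, seed=4)[1].row_ids
        b = split_holdout(fm, 0.25, seed=4)[1].row_ids
        assert a == b
        c = split_holdout(fm, 0.25, seed=5)[1].row_ids
        assert a != c

    def test_grouped_keeps_replicates_together(self):
        fm = self._study_matrix()
        train, val = split_holdout(fm, 0.25, seed=2, group_replicates=True)
        assert not set(train.groups) & set(val.groups)
        # 105 tissues -> floor(26.25) = 26 tissues = 52 slides
        assert val.n == 52

    def test_small_stratum_rejected(self):
        fm = make_fm(np.zeros((3, 2)), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            split_holdout(fm, 0.5, seed=0)

    def test_bad_frac(self):
        fm = self._study_matrix()
        with pytest.raises(ValueError):
            split_holdout(fm, 1.5)


class TestFitPLSR:
    def test_rank1_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = np.zeros((12, 6))
        X[:, 2] = rng.normal(size=12)
        y = 3.0 * X[:, 2]
        y = y - y.min()  # y >= 0, still exactly linear in column 2
        model = fit_plsr(make_fm(X, y), 1)
        pred = predict(model, X)
        np.testing.assert_allclose(pred, y, atol=1e-9)
        assert np.argmax(np.abs(model.coefficients)) == 2

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = np.abs(rng.normal(size=30)) * 5
        model = fit_plsr(make_fm(X, y), 4)
        # OLS oracle via normal equations on centered data
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols_pred = y.mean() + Xc @ beta
        np.testing.assert_allclose(predict(model, X), ols_pred, atol=1e-6)

    def test_weights_unit_norm_scores_orthogonal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 15))
        y = np.abs(rng.normal(size=20))
        model = fit_plsr(make_fm(X, y), 5)
        np.testing.assert_allclose(np.linalg.norm(model.weights, axis=1), 1.0, atol=1e-10)
        # reconstruct scores by sequential deflation and check orthogonality
        Xd = X - X.mean(axis=0)
        scores = []
        for w, p in zip(model.weights, model.x_loadings):
            s = Xd @ w
            scores.append(s)
            Xd = Xd - np.outer(s, p)
        S = np.array(scores)
        gram = S @ S.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 8))
        y = np.abs(rng.normal(size=15))
        perm = rng.permutation(15)
        a = fit_plsr(make_fm(X, y), 3)
        b = fit_plsr(make_fm(X[perm], y[perm]), 3)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            fit_plsr(make_fm(np.random.default_rng(0).normal(size=(5, 3)), np.full(5, 2.0)), 1)

    def test_excess_components_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fit_plsr(make_fm(rng.normal(size=(5, 3)), np.abs(rng.normal(size=5))), 5)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_nipals_matches_svd_oracle(self, k):
        """Acceptance-grade oracle: random 20x15 problems, NIPALS
        predictions equal the independent SVD-based oracle within 1e-6."""
        rng = np.random.default_rng(k)
        X = rng.normal(size=(20, 15))
        y = np.abs(rng.normal(size=20)) * 3
        model = fit_plsr(make_fm(X, y), k)
        oracle = svd_pls_oracle(X, y, k)
        Xnew = rng.normal(size=(8, 15))
        np.testing.assert_allclose(predict(model, Xnew), oracle(Xnew), atol=1e-6)

    def test_nipals_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 10))
        y = np.abs(rng.normal(size=25))
        model = fit_plsr(make_fm(X, y), 4)
        sk = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(
            predict(model, X), sk.predict(X).ravel(), atol=1e-8
        )

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 6))
        y = np.abs(rng.normal(size=10))
        model = fit_plsr(make_fm(X, y), 2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PLSRModel.from_json(path)
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        np.testing.assert_allclose(predict(back, X), predict(model, X))


class TestPredict:
    def test_centering_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        y = np.abs(rng.normal(size=10))
        model = fit_plsr(make_fm(X, y), 2)
        assert predict(model, model.x_mean)[0] == pytest.approx(model.y_mean)

    def test_nullspace_vector_no_effect(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        y = np.abs(rng.normal(size=12))
        model = fit_plsr(make_fm(X, y), 2)
        # build a vector orthogonal to the coefficients
        v = rng.normal(size=5)
        v -= (v @ model.coefficients) / (model.coefficients @ model.coefficients) * model.coefficients
        x = X[3]
        assert predict(model, x + v)[0] == pytest.approx(predict(model, x)[0], abs=1e-10)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(6)
        model = fit_plsr(make_fm(rng.normal(size=(8, 4)), np.abs(rng.normal(size=8))), 1)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 7)))


class TestSelectComponents:
    def test_two_latent_factors(self):
        rng = np.random.default_rng(8)
        t1, t2 = rng.normal(size=(2, 60))
        load = rng.normal(size=(2, 12))
        X = np.outer(t1, load[0]) + np.outer(t2, load[1]) + 1e-8 * rng.normal(size=(60, 12))
        y = np.abs(2 * t1 - t2)
        y = y - y.min()
        k, diag = select_components(make_fm(X, y), max_components=6, folds=2, seed=0)
        assert k == 2

    def test_max_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 5))
        y = np.abs(X @ rng.normal(size=5))
        k, _ = select_components(make_fm(X, y), max_components=1)
        assert k == 1

    def test_pure_noise_returns_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 10))
        y = np.abs(rng.normal(size=40))  # independent of X
        k, _ = select_components(make_fm(X, y), max_components=8, folds=2, seed=1)
        assert k == 1

    def test_diagnostics_table(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 6))
        y = np.abs(X @ rng.normal(size=6))
        k, diag = select_components(make_fm(X, y), max_components=4)
        assert list(diag.columns) == [
            "n_components", "cv_mse", "variance_explained_x", "variance_explained_y",
        ]
        assert len(diag) == 4

    def test_bad_folds(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            select_components(make_fm(rng.normal(size=(10, 3)), np.abs(rng.normal(size=10))), folds=1)


class TestEvaluate:
    def test_perfect(self):
        rep = evaluate(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert rep.mae == 0.0
        np.testing.assert_array_equal(rep.cdf, [0.0, 0.0])

    def test_mae_arithmetic(self):
        rep = evaluate(np.array([1.0, 2.0, 3.0]), np.array([0.0, 0.0, 0.0]))
        assert rep.mae == pytest.approx(2.0)

    def test_duplication_invariance(self):
        p = np.array([1.0, 3.0])
        t = np.array([0.0, 0.0])
        assert evaluate(p, t).mae == evaluate(np.tile(p, 2), np.tile(t, 2)).mae

    def test_cdf_non_decreasing(self):
        rng = np.random.default_rng(1)
        rep = evaluate(rng.normal(size=20), rng.normal(size=20))
        assert np.all(np.diff(rep.cdf) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([]), np.array([]))


class TestCoefficientSpectrum:
    def test_zero_variance_column(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(15, 4))
        X[:, 1] = 7.0  # constant column
        y = np.abs(X[:, 0])
        model = fit_plsr(make_fm(X, y), 2)
        table = coefficient_spectrum(model)
        assert table.coefficient[1] == pytest.approx(0.0, abs=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 3))
        y = 2.0 * X[:, 0]
        y = y - y.min()  # keep y >= 0
        model = fit_plsr(make_fm(X, y), 1)
        table = coefficient_spectrum(model)
        assert table.coefficient[0] > 0  # absorbance up -> predicted time up
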