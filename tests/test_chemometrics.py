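"""PLS regression, preprocessing and the cross-validation schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qclspec.chemometrics import (
    CVResult,
    PLSModel,
    PreprocessConfig,
    best_result,
    cross_validate,
    make_folds,
    pls_fit,
    preprocess,
    r2,
    rmse,
)


class TestPreprocess:
    def test_savgol_preserves_low_degree_polynomials(self):
        x = np.linspace(0, 1, 60)
        poly = 2.0 - 3.0 * x + 0.5 * x**2
        cfg = PreprocessConfig(standardize=False)
        out, _ = preprocess(poly[None, :], cfg)
        np.testing.assert_allclose(out[0], poly, atol=1e-10)

    def test_standardised_training_matrix(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 3.0, size=(40, 25))
        out, _ = preprocess(X, PreprocessConfig())
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-10)

    def test_heldout_uses_training_statistics(self):
        rng = np.random.default_rng(1)
        train = rng.normal(0.0, 1.0, size=(30, 20))
        test = rng.normal(5.0, 2.0, size=(10, 20))
        _, stats = preprocess(train, PreprocessConfig())
        with_train, _ = preprocess(test, PreprocessConfig(), stats=stats)
        self_std, _ = preprocess(test, PreprocessConfig())
        assert not np.allclose(with_train, self_std)
        # held-out data standardised with foreign stats keeps its own offset
        assert np.abs(with_train.mean()) > 1.0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(savgol_window=8)
        with pytest.raises(ValueError):
            PreprocessConfig(savgol_window=3, savgol_polyorder=4)
        with pytest.raises(ValueError, match="shorter"):
            preprocess(np.ones((2, 5)), PreprocessConfig(savgol_window=9))


class TestPLS:
    def test_single_factor_data_one_component(self):
        rng = np.random.default_rng(2)
        X = np.zeros((20, 15))
        X[:, 4] = rng.uniform(0, 1, 20)
        y = 3.0 * X[:, 4]
        m = pls_fit(X, y, 1)
        np.testing.assert_allclose(m.predict(X, 1), y, atol=1e-10)

    def test_full_rank_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        m = pls_fit(X, y, 6)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        ols = Xc @ beta + y.mean()
        np.testing.assert_allclose(m.predict(X, 6), ols, atol=1e-8)

    def test_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 12))
        Y = rng.normal(size=(30, 2))
        ours = pls_fit(X, Y[:, 0], 4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, Y[:, 0])
        np.testing.assert_allclose(
            ours.predict(X, 4), ref.predict(X).ravel(), atol=1e-10
        )
        ours2 = pls_fit(X, Y, 4, mode="pls2")
        ref2 = sklearn.PLSRegression(
            n_components=4, scale=False, tol=1e-12, max_iter=5000
        ).fit(X, Y)
        np.testing.assert_allclose(ours2.predict(X, 4), ref2.predict(X), atol=1e-5)

    def test_noiseless_four_analyte_mixture_recovered_with_four_lvs(self):
        rng = np.random.default_rng(5)
        C = rng.uniform(0.0, 1.0, size=(25, 4))
        spectra_lib = rng.uniform(0.0, 1.0, size=(4, 80))
        X = C @ spectra_lib
        m = pls_fit(X, C, 4)
        pred = m.predict(X, 4)
        assert rmse(pred.ravel(), C.ravel()) < 1e-6

    def test_rank_deficient_stops_with_warning(self):
        X = np.outer(np.arange(10.0), np.ones(6))  # rank 1
        y = np.arange(10.0)
        with pytest.warns(UserWarning, match="rank-deficient"):
            m = pls_fit(X, y, 4)
        assert m.n_achieved_ == 1

    def test_component_bounds_enforced(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="exceeds"):
            pls_fit(X, y, 10)
        with pytest.raises(ValueError):
            PLSModel(0)


class TestMetrics:
    def test_rmse_hand_value(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(
            np.sqrt(1.0 / 3.0)
        )

    def test_perfect_and_mean_predictor(self):
        ref = np.array([1.0, 2.0, 5.0])
        assert rmse(ref, ref) == 0.0
        assert r2(ref, ref) == 1.0
        assert r2(np.full(3, ref.mean()), ref) == pytest.approx(0.0)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r2(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    @given(k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_rmse_scale_equivariance(self, k):
        rng = np.random.default_rng(6)
        pred = rng.normal(size=20)
        ref = rng.normal(size=20)
        assert rmse(k * pred, k * ref) == pytest.approx(k * rmse(pred, ref), rel=1e-9)


class TestFolds:
    def test_loocv_one_fold_per_measurement(self):
        folds = make_folds(np.arange(25), np.zeros(25, int), "loocv")
        assert len(np.unique(folds)) == 25

    def test_l5ocv_blocks_of_five_within_series(self):
        sample_ids = np.tile(np.arange(25), 2)
        series_ids = np.repeat([0, 1], 25)
        folds = make_folds(sample_ids, series_ids, "l5ocv")
        assert len(np.unique(folds)) == 10
        for f in np.unique(folds):
            members = folds == f
            assert members.sum() == 5
            assert len(np.unique(series_ids[members])) == 1  # never crosses series
            ids = np.sort(sample_ids[members])
            np.testing.assert_array_equal(ids, np.arange(ids[0], ids[0] + 5))

    def test_ldocv_one_fold_per_series(self):
        folds = make_folds(np.tile(np.arange(25), 4), np.repeat(np.arange(4), 25), "ldocv")
        assert len(np.unique(folds)) == 4

    def test_ldocv_requires_two_series(self):
        with pytest.raises(ValueError, match="2 series"):
            make_folds(np.arange(10), np.zeros(10, int), "ldocv")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            make_folds(np.arange(10), np.zeros(10, int), "l7ocv")


class TestCrossValidate:
    def _exact_dataset(self, n=30, p=40, seed=7):
        rng = np.random.default_rng(seed)
        C = rng.uniform(0.0, 800.0, size=(n, 2))
        lib = rng.uniform(0.0, 1e-4, size=(2, p))
        return C @ lib, C

    def test_perfect_predictor_all_schemes(self):
        X, Y = self._exact_dataset()
        ids = np.arange(30)
        series = np.repeat([0, 1, 2], 10)
        for scheme in ("loocv", "l5ocv", "ldocv"):
            results = cross_validate(
                X, Y, ids, series, scheme, max_lv=3,
                preprocess_config=PreprocessConfig(savgol_window=5),
                analyte_names=["a", "b"],
            )
            best = best_result(results, "a")
            assert best.rmsecv["a"] < 1e-6
            assert best.r2["a"] > 1 - 1e-12

    def test_results_cover_requested_lv_range(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 40))
        Y = rng.normal(size=(30, 2)) * 100.0
        results = cross_validate(
            X, Y, np.arange(30), np.repeat([0, 1, 2], 10), "loocv", max_lv=4,
            preprocess_config=PreprocessConfig(savgol_window=5),
        )
        assert [r.n_lv for r in results] == [1, 2, 3, 4]
        assert all(isinstance(r, CVResult) for r in results)

    def test_ldocv_harder_than_loocv_with_series_offset(self):
        """A per-series additive baseline direction hurts predictions for an
        unseen series much more than for an unseen single measurement."""
        rng = np.random.default_rng(8)
        n_series, per = 4, 15
        C = np.tile(rng.uniform(0.0, 800.0, per), n_series)
        lib = rng.uniform(0.0, 1.0, 50)
        X = np.outer(C, lib * 1e-4)
        X += rng.normal(0.0, 2e-4, X.shape)
        series = np.repeat(np.arange(n_series), per)
        for s in range(n_series):
            X[series == s] += rng.normal(0.0, 2e-3) * rng.uniform(0, 1, 50)
        ids = np.tile(np.arange(per), n_series)
        loo = best_result(
            cross_validate(X, C, ids, series, "loocv", max_lv=5), "analyte_0"
        )
        ldo = best_result(
            cross_validate(X, C, ids, series, "ldocv", max_lv=5), "analyte_0"
        )
        assert ldo.rmsecv["analyte_0"] >= loo.rmsecv["analyte_0"]

    def test_max_lv_capacity_check(self):
        X, Y = self._exact_dataset(n=12)
        with pytest.raises(ValueError, match="capacity"):
            cross_validate(X, Y, np.arange(12), np.repeat([0, 1], 6), "ldocv",
                           max_lv=8)
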