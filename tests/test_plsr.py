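"""NIPALS PLS1: oracle equivalences, invariances, LV selection."""

import numpy as np
import pytest

from nirtransfer.plsr import (
    PLSModel,
    fit_pls1,
    predict,
    predict_scores,
    select_n_lv_loo,
)
from nirtransfer.spectra_io import ReferenceTable

from conftest import make_spectra


def ref_for(spectra, values, analyte="sucrose"):
    return ReferenceTable(
        sample_ids=list(spectra.sample_ids), analyte=analyte, values=values
    )


class TestFitPls1:
    def test_exact_single_channel_relation(self, rng):
        # only channel 3 varies; y is exactly linear in it -> 1 LV suffices
        X = np.full((12, 8), 0.5)
        X[:, 3] = rng.normal(0.5, 0.1, 12)
        y = 10.0 + 40.0 * X[:, 3]
        spectra = make_spectra(X)
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=1)
        fitted = predict(model, spectra)
        rmsec = np.sqrt(np.mean((fitted - y) ** 2))
        assert rmsec < 1e-8

    def test_full_lv_equals_least_squares(self, rng):
        # full-LV PLS1 on full-rank data == OLS via pseudo-inverse
        for trial in range(5):
            X = rng.normal(0.0, 1.0, (10, 8))
            y = np.clip(rng.uniform(10, 40, 10), 0, 100)
            spectra = make_spectra(X + 1.0)
            model = fit_pls1(spectra, ref_for(spectra, y), n_lv=8)
            Xc = X + 1.0 - (X + 1.0).mean(axis=0)
            beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
            ols = Xc @ beta + y.mean()
            np.testing.assert_allclose(predict(model, spectra), ols, atol=1e-6)

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(0.5, 0.1, (9, 15))
        y = rng.uniform(5, 50, 9)
        spectra = make_spectra(X)
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=3)
        perm = rng.permutation(9)
        spectra_p = make_spectra(X[perm], ids=[f"s{i}" for i in perm])
        y_p = ref_for(spectra_p, y[perm])
        model_p = fit_pls1(spectra_p, y_p, n_lv=3)
        np.testing.assert_allclose(
            model.regression_vector, model_p.regression_vector, atol=1e-10
        )

    def test_scores_orthogonal(self, rng):
        X = rng.normal(0.5, 0.1, (14, 20))
        y = rng.uniform(5, 50, 14)
        spectra = make_spectra(X)
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=5)
        Xc = X - X.mean(axis=0)
        R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
        T = Xc @ R
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_matches_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(0.5, 0.2, (15, 30))
        y = rng.uniform(5, 50, 15)
        spectra = make_spectra(X)
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=4)
        sk = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(
            predict(model, spectra), sk.predict(X).ravel(), atol=1e-8
        )

    def test_zero_variance_y_rejected(self, random_spectra):
        y = ref_for(random_spectra, np.full(10, 20.0))
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls1(random_spectra, y, n_lv=2)

    def test_n_lv_out_of_range(self, random_spectra, rng):
        y = ref_for(random_spectra, rng.uniform(5, 50, 10))
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls1(random_spectra, y, n_lv=10)  # n-1 = 9 is the cap


class TestPredict:
    def test_training_set_reproduces_fitted_values(self, rng):
        X = rng.normal(0.5, 0.1, (10, 12))
        y = rng.uniform(5, 50, 10)
        spectra = make_spectra(X)
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=3)
        p1 = predict(model, spectra)
        p2 = predict(model, spectra)
        np.testing.assert_array_equal(p1, p2)

    def test_centered_zero_spectrum_predicts_y_center(self, rng):
        X = rng.normal(0.5, 0.1, (10, 12))
        y = rng.uniform(5, 50, 10)
        spectra = make_spectra(X)
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=2)
        at_center = make_spectra(model.x_center.column_means[None, :])
        assert predict(model, at_center)[0] == pytest.approx(model.y_center)

    def test_score_space_path_agrees(self, rng):
        X = rng.normal(0.5, 0.1, (12, 18))
        y = rng.uniform(5, 50, 12)
        spectra = make_spectra(X)
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=4)
        other = make_spectra(rng.normal(0.5, 0.1, (6, 18)))
        np.testing.assert_allclose(
            predict(model, other), predict_scores(model, other), atol=1e-9
        )

    def test_prediction_affine_in_input(self, rng):
        X = rng.normal(0.5, 0.1, (10, 12))
        y = rng.uniform(5, 50, 10)
        spectra = make_spectra(X)
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=3)
        a, b_ = make_spectra(X[:1] * 1.7), make_spectra(X[1:2] * 0.4)
        mix = make_spectra(0.3 * a.absorbance + 0.7 * b_.absorbance)
        lhs = predict(model, mix)[0] - model.y_center
        rhs = 0.3 * (predict(model, a)[0] - model.y_center) + 0.7 * (
            predict(model, b_)[0] - model.y_center
        )
        # affine: offsets combine because the weights sum to 1
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_strict_pretreatment_check(self, rng):
        X = rng.normal(0.5, 0.1, (10, 12))
        y = rng.uniform(5, 50, 10)
        spectra = make_spectra(X, tags=["snv"])
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=2)
        raw = make_spectra(X)
        with pytest.raises(ValueError, match="pretreatment"):
            predict(model, raw, strict=True)

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.normal(0.5, 0.1, (10, 12))
        y = rng.uniform(5, 50, 10)
        spectra = make_spectra(X, tags=["snv"])
        model = fit_pls1(spectra, ref_for(spectra, y), n_lv=3)
        model.to_json(tmp_path / "m.json")
        back = PLSModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(
            back.regression_vector, model.regression_vector
        )
        assert back.grid == model.grid
        np.testing.assert_array_equal(predict(back, spectra), predict(model, spectra))


class TestLooSelection:
    def test_recovers_rank_two_system(self, rng):
        # X built from exactly 2 latent factors; y depends on both
        n, p = 20, 30
        t1, t2 = rng.normal(size=n), rng.normal(size=n)
        p1, p2 = rng.normal(size=p), rng.normal(size=p)
        X = np.outer(t1, p1) + np.outer(t2, p2)
        y = np.clip(25 + 5 * t1 + 3 * t2, 0, 100)
        spectra = make_spectra(X + 2.0)
        cv = select_n_lv_loo(spectra, ref_for(spectra, y), max_lv=6)
        assert cv.chosen_n_lv == 2

    def test_noise_keeps_model_small(self, rng):
        n, p = 24, 40
        x_info = rng.normal(size=n)
        X = rng.normal(0, 0.05, (n, p))
        X[:, 7] += x_info
        y = np.clip(25 + 6 * x_info + rng.normal(0, 0.2, n), 0, 100)
        spectra = make_spectra(X + 1.0)
        cv = select_n_lv_loo(spectra, ref_for(spectra, y), max_lv=10)
        assert cv.chosen_n_lv <= 4
        assert cv.rmsecv[cv.chosen_n_lv] <= min(cv.rmsecv.values()) + 1e-12

    def test_tie_broken_toward_fewer_lvs(self, rng):
        # rank-1 noiseless system: every LV count >= 1 gives identical
        # RMSECV, so the tie rule must pick 1
        n, p = 12, 10
        t = rng.normal(size=n)
        load = rng.normal(size=p)
        X = np.outer(t, load) + 1.0
        y = np.clip(25 + 4 * t, 0, 100)
        spectra = make_spectra(X)
        cv = select_n_lv_loo(spectra, ref_for(spectra, y), max_lv=4)
        assert cv.chosen_n_lv == 1
        vals = list(cv.rmsecv.values())
        assert max(vals) - min(vals) < 1e-9

    def test_max_lv_validation(self, random_spectra, rng):
        y = ref_for(random_spectra, rng.uniform(5, 50, 10))
        with pytest.raises(ValueError, match="max_lv"):
            select_n_lv_loo(random_spectra, y, max_lv=9)  # cap is n-2 = 8
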