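"""Univariate OLS lines and the full-spectrum PLS baseline."""

import numpy as np
import pytest

from ltindex.indices import BandPair, LinearIndexSpec
from ltindex.regression_models import (
    DegenerateFitError,
    GridMismatchError,
    artifact_to_model,
    fit_index_model,
    fit_pls,
    fit_univariate,
    model_to_artifact,
    predict,
)
from ltindex.spectra_io import read_model_artifact, write_model_artifact
from conftest import make_spectrum_set


class TestFitUnivariate:
    def test_exact_line(self):
        x = np.array([0.1, 0.4, 0.7, 0.9])
        fit = fit_univariate(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        # x̄ = 1, ȳ = 16/3, Sxy = 3, Sxx = 2 → slope 3/2, intercept 23/6,
        # SSres = 1/6, SStot = 14/3 → R² = 27/28
        fit = fit_univariate([0.0, 1.0, 2.0], [4.0, 5.0, 7.0])
        assert fit.slope == pytest.approx(1.5, abs=1e-12)
        assert fit.intercept == pytest.approx(23.0 / 6.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(27.0 / 28.0, abs=1e-12)

    def test_uncorrelated_noise_near_zero_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        y = 5.0 + rng.normal(size=2000)
        assert fit_univariate(x, y).r_squared < 0.01

    def test_constant_index_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_univariate([0.3, 0.3, 0.3], [4.0, 5.0, 6.0])

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=50)
        y = 1.0 + 3.0 * x + rng.normal(0, 0.2, 50)
        fit = fit_univariate(x, y)
        assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2,
                                              abs=1e-12)


class TestIndexModelPredict:
    def planted(self):
        rng = np.random.default_rng(2)
        R = rng.uniform(0.2, 0.8, (20, 4))
        ssc = 3.0 * (R[:, 0] - R[:, 2]) + 5.0
        return make_spectrum_set(R, ssc, wavelengths=[700, 710, 720, 730])

    def test_calibration_predictions_reproduce_fit(self):
        ss = self.planted()
        model = fit_index_model(ss, "DSI", bands=BandPair(700.0, 720.0))
        np.testing.assert_allclose(predict(model, ss), ss.ssc, atol=1e-10)

    def test_lt_model_constant_spectrum_closed_form(self):
        ss = self.planted()
        spec = LinearIndexSpec("ltDSI", BandPair(700.0, 720.0),
                               k1=2.0, k2=1.0, b=0.5)
        model = fit_index_model(ss, "ltDSI", spec=spec)
        const = make_spectrum_set(np.full((1, 4), 0.4), [5.0],
                                  wavelengths=[700, 710, 720, 730])
        want = model.line.intercept + model.line.slope * (2.0 * 0.4 - 0.4 + 0.5)
        assert predict(model, const)[0] == pytest.approx(want, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        ss = self.planted()
        model = fit_index_model(ss, "DSI", bands=BandPair(700.0, 720.0))
        other = make_spectrum_set(np.full((1, 2), 0.4), [5.0],
                                  wavelengths=[800, 810])
        with pytest.raises(GridMismatchError):
            predict(model, other)

    def test_artifact_round_trip_preserves_predictions(self, tmp_path):
        ss = self.planted()
        spec = LinearIndexSpec("ltNDSI", BandPair(700.0, 730.0),
                               k1=1.1, k2=0.9, b1=0.05, b2=0.2)
        model = fit_index_model(ss, "ltNDSI", spec=spec)
        path = tmp_path / "m.json"
        write_model_artifact(model_to_artifact(model), path)
        back = artifact_to_model(read_model_artifact(path))
        np.testing.assert_allclose(predict(back, ss), predict(model, ss),
                                   atol=1e-12)


class TestPLS:
    def test_response_in_predictor_span_perfect_with_two_lvs(self):
        rng = np.random.default_rng(4)
        n, p = 40, 6
        X = rng.uniform(0.1, 0.9, (n, p))
        beta = np.zeros(p)
        beta[[1, 4]] = [2.0, -1.5]
        y = 5.0 + (X - X.mean(0)) @ beta
        ss = make_spectrum_set(X, y)
        model = fit_pls(ss, max_lv=6)
        # full-rank PLS reproduces the OLS projection; with enough LVs R² = 1
        assert model.explained_variance[-1] == pytest.approx(1.0, abs=1e-8)

    def test_full_rank_pls_matches_ols_predictions(self):
        rng = np.random.default_rng(5)
        n, p = 30, 5
        X = rng.uniform(0.1, 0.9, (n, p))
        y = 4.0 + X @ rng.normal(size=p) + 0.05 * rng.normal(size=n)
        ss = make_spectrum_set(X, y)
        model = fit_pls(ss, max_lv=p, lv_rule={"min_gain": -1.0})  # force all LVs
        Xc = X - X.mean(0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        ols_pred = y.mean() + Xc @ beta
        np.testing.assert_allclose(predict(model, ss), ols_pred, atol=1e-8)

    def test_duplicated_columns_match_deduplicated_fit(self):
        rng = np.random.default_rng(6)
        n, p = 30, 4
        X = rng.uniform(0.1, 0.9, (n, p))
        y = 5.0 + X @ np.array([1.0, -0.5, 0.3, 0.2]) + 0.05 * rng.normal(size=n)
        ss1 = make_spectrum_set(X, y, wavelengths=[700, 710, 720, 730])
        Xdup = np.hstack([X, X[:, [1]]])
        ss2 = make_spectrum_set(Xdup, y, wavelengths=[700, 710, 720, 730, 740])
        # at full rank PLS reproduces the OLS projection, which is identical
        # for the duplicated and deduplicated column spaces
        m1 = fit_pls(ss1, max_lv=4, lv_rule={"min_gain": -1.0})
        m2 = fit_pls(ss2, max_lv=4, lv_rule={"min_gain": -1.0})
        np.testing.assert_allclose(predict(m1, ss1), predict(m2, ss2), atol=1e-6)

    def test_orthogonal_response_near_zero_r2(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0.1, 0.9, (200, 5))
        y = np.full(200, 5.0) + 0.0 * X[:, 0]
        y[0] += 1e-9  # avoid an exactly constant response
        ss = make_spectrum_set(X, y)
        model = fit_pls(ss, max_lv=3)
        assert model.explained_variance[-1] < 0.05

    def test_pls_artifact_round_trip(self, tmp_path, bench_cohort):
        ss, _ = bench_cohort
        model = fit_pls(ss, max_lv=5)
        path = tmp_path / "pls.json"
        write_model_artifact(model_to_artifact(model), path)
        back = artifact_to_model(read_model_artifact(path))
        assert back.n_latent_variables == model.n_latent_variables
        np.testing.assert_allclose(predict(back, ss), predict(model, ss),
                                   atol=1e-12)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(8)
        ss = make_spectrum_set(rng.uniform(0.1, 0.9, (4, 6)),
                               [4.0, 5.0, 6.0, 7.0])
        with pytest.raises(ValueError):
            fit_pls(ss, max_lv=5)
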