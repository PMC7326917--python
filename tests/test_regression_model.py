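"""Tolerance-model fitting, prediction, and correlation diagnostics."""

import numpy as np
import pandas as pd
import pytest

from germscreen import (
    GermscreenError,
    ToleranceModel,
    correlation_matrix,
    fit_tolerance_model,
    load_model_json,
    per_trait_r2,
    predict_y,
    published_grade_scheme,
    published_model,
    save_model_json,
    standardized_coefficients,
    validate_model,
)
from germscreen.panel_io import TRAITS
from germscreen.published import PUBLISHED_STI_ROWS


def mfv_panel(n=60, seed=5, zero_min=False):
    """Random STI matrix plus the mean MFV it induces (affine construction)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.05, 1.3, size=(n, len(TRAITS)))
    if zero_min:
        X[0] = 0.0
    lo, hi = X.min(axis=0), X.max(axis=0)
    y = ((X - lo) / (hi - lo)).mean(axis=1)
    return X, y, lo, hi


class TestFit:
    def test_closed_form_coefficients_on_complete_panel(self):
        X, y, lo, hi = mfv_panel()
        model = fit_tolerance_model(X, y)
        expected = 1 / (7 * (hi - lo))
        assert model.coef_array() == pytest.approx(expected, rel=1e-9)
        assert model.intercept == pytest.approx(-(lo / (7 * (hi - lo))).sum(), abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert validate_model(model, X, y)["max_abs_diff"] <= 1e-10

    def test_intercept_vanishes_when_every_trait_min_is_zero(self):
        X, y, lo, hi = mfv_panel(zero_min=True)
        model = fit_tolerance_model(X, y)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        X, y, *_ = mfv_panel(seed=8)
        y = y + rng.normal(0, 0.02, size=len(y))   # break exactness
        model = fit_tolerance_model(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert model.intercept == pytest.approx(ref.params[0], rel=1e-8)
        assert model.coef_array() == pytest.approx(ref.params[1:], rel=1e-8)
        assert model.r_squared == pytest.approx(ref.rsquared, rel=1e-8)

    def test_ols_optimality_under_perturbation(self):
        rng = np.random.default_rng(9)
        X, y, *_ = mfv_panel(seed=9)
        y = y + rng.normal(0, 0.05, size=len(y))
        model = fit_tolerance_model(X, y)
        design = np.column_stack([np.ones(len(y)), X])
        beta = np.concatenate([[model.intercept], model.coef_array()])
        rss = np.sum((y - design @ beta) ** 2)
        for j in range(len(beta)):
            for eps in (-1e-4, 1e-4):
                perturbed = beta.copy()
                perturbed[j] += eps
                assert np.sum((y - design @ perturbed) ** 2) > rss

    def test_constant_trait_named_in_error(self):
        X, y, *_ = mfv_panel(n=30)
        X[:, TRAITS.index("GE")] = 0.5
        with pytest.raises(GermscreenError, match="GE"):
            fit_tolerance_model(X, y)

    def test_too_few_rows_rejected(self):
        X, y, *_ = mfv_panel(n=60)
        with pytest.raises(GermscreenError, match="at least"):
            fit_tolerance_model(X[:5], y[:5])


class TestPredict:
    @pytest.mark.parametrize(
        "germplasm", ["152505", "156004", "152237", "151072", "152059"]
    )
    def test_published_model_reproduces_printed_y(self, germplasm):
        stis, _, printed_y = PUBLISHED_STI_ROWS[germplasm]
        y = predict_y(published_model(), np.array(stis))
        # 5e-4: worst-case propagation of the printed 3-decimal STI rounding
        assert y == pytest.approx(printed_y, abs=5e-4)

    def test_all_zero_profile_scores_the_intercept(self):
        assert predict_y(published_model(), np.zeros(7)) == pytest.approx(0.0, abs=1e-12)

    def test_prediction_is_affine(self):
        model = published_model()
        rng = np.random.default_rng(2)
        p1, p2 = rng.uniform(0, 1.2, size=(2, 7))
        for a in (0.0, 0.3, 1.0):
            mix = a * p1 + (1 - a) * p2
            assert predict_y(model, mix) == pytest.approx(
                a * predict_y(model, p1) + (1 - a) * predict_y(model, p2)
            )

    def test_missing_sti_rejected(self):
        with pytest.raises(GermscreenError, match="missing"):
            predict_y(published_model(), {t: 0.5 for t in TRAITS[:-1]})

    def test_one_trait_model_identity(self):
        model = ToleranceModel(
            coefficients={t: (1.0 if t == "GR" else 0.0) for t in TRAITS},
            intercept=0.0,
        )
        assert predict_y(model, dict.fromkeys(TRAITS, 0.42)) == pytest.approx(0.42)


class TestValidation:
    def test_training_panel_differences_are_numerical_noise(self):
        X, y, *_ = mfv_panel(seed=4)
        model = fit_tolerance_model(X, y)
        stats = validate_model(model, X, y)
        assert stats["max_abs_diff"] <= 1e-10
        assert stats["min_abs_diff"] <= stats["mean_abs_diff"] <= stats["max_abs_diff"]

    def test_printed_verification_rows_within_published_bound(self):
        # the published panel's max |Y - mean MFV| was 0.002949; the printed
        # verification rows must stay within 0.003
        model = published_model()
        diffs = [
            abs(predict_y(model, np.array(stis)) - mean)
            for stis, mean, _ in PUBLISHED_STI_ROWS.values()
        ]
        assert max(diffs) <= 0.003

    def test_empty_panel_rejected(self):
        model = published_model()
        with pytest.raises(GermscreenError, match="non-empty"):
            validate_model(model, np.empty((0, 7)), np.empty(0))


class TestDiagnostics:
    def test_correlation_matrix_matches_definition(self):
        X, y, *_ = mfv_panel(seed=6)
        corr = correlation_matrix(X, y).to_numpy()
        data = np.column_stack([X, y])
        n = data.shape[0]
        centred = data - data.mean(axis=0)
        cov = centred.T @ centred / n
        sd = np.sqrt(np.diag(cov))
        brute = cov / np.outer(sd, sd)
        assert corr == pytest.approx(brute, abs=1e-12)

    def test_correlation_matrix_symmetric_psd_unit_diagonal(self):
        X, y, *_ = mfv_panel(seed=7)
        corr = correlation_matrix(X, y).to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.diag(corr) == pytest.approx(np.ones(8))
        assert np.linalg.eigvalsh(corr).min() >= -1e-10
        assert np.abs(corr).max() <= 1 + 1e-12

    def test_per_trait_r2_is_squared_pearson(self):
        X, y, *_ = mfv_panel(seed=10)
        corr = correlation_matrix(X, y)
        r2 = per_trait_r2(X, y)
        for t in TRAITS:
            assert r2[t] == pytest.approx(corr.loc[t, "mean_MFV"] ** 2)
            assert 0 <= r2[t] <= 1

    def test_r2_extremes(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(size=(400, 7))
        y = X[:, 0].copy()          # mean MFV equals the GR column
        r2 = per_trait_r2(X, y)
        assert r2["GR"] == pytest.approx(1.0)
        assert r2["GI"] < 0.05      # independent column: R^2 near 0

    def test_standardized_coefficients_match_zscore_refit(self):
        X, y, *_ = mfv_panel(seed=14)
        rng = np.random.default_rng(14)
        y = y + rng.normal(0, 0.03, size=len(y))
        model = fit_tolerance_model(X, y)
        std = standardized_coefficients(model, X, y)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        z_y = (y - y.mean()) / y.std(ddof=1)
        refit = fit_tolerance_model(Z, z_y)
        for t in TRAITS:
            assert std[t] == pytest.approx(refit.coefficients[t], rel=1e-8)

    def test_standardized_coefficients_scale_invariant(self):
        X, y, *_ = mfv_panel(seed=15)
        model = fit_tolerance_model(X, y)
        X2 = X.copy()
        X2[:, 0] *= 10
        model2 = fit_tolerance_model(X2, y)
        assert model2.coefficients["GR"] == pytest.approx(
            model.coefficients["GR"] / 10, rel=1e-8
        )
        assert standardized_coefficients(model2, X2, y)["GR"] == pytest.approx(
            standardized_coefficients(model, X, y)["GR"], rel=1e-8
        )


class TestModelJson:
    def test_round_trip_with_scheme(self, tmp_path):
        model = published_model()
        scheme = published_grade_scheme()
        path = tmp_path / "model.json"
        save_model_json(path, model, scheme)
        loaded, loaded_scheme = load_model_json(path)
        assert loaded.coefficients == model.coefficients
        assert loaded.intercept == model.intercept
        assert loaded_scheme.cuts == scheme.cuts
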