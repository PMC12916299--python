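"""HC3 moderated regression, Johnson-Neyman probing, control analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ctenrich as ce
from ctenrich.outcome import (MODEL_TERMS, ModeratedOutcomeModel, OutcomeFit,
                              jn_table)
from ctenrich.simulate import OutcomeSpec, simulate_outcome_table


def _design_from_table(tab):
    return pd.DataFrame({
        "age": tab["age"],
        "bmi_sds_baseline": tab["bmi_sds_baseline"],
        "spect": tab["spect"],
        "bmi_sds_baseline:spect": tab["bmi_sds_baseline"] * tab["spect"],
    })


def _fit_table(tab):
    tab = tab.dropna()
    est = ModeratedOutcomeModel().fit(_design_from_table(tab),
                                      tab["delta_bmi_sds"])
    w = tab["bmi_sds_baseline"]
    return OutcomeFit("main", "SERT", est, (float(w.min()), float(w.max())))


class TestHC3:
    def test_zero_residuals_give_zero_matrix(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(8), rng.standard_normal(8)])
        assert np.abs(ce.hc3_covariance(X, np.zeros(8))).max() == 0.0

    def test_fixed_design_matches_elementwise_hand_computation(self):
        X = np.array([[1.0, 0.2], [1.0, -1.3], [1.0, 0.7], [1.0, 2.1],
                      [1.0, -0.4], [1.0, 1.0]])
        e = np.array([0.3, -0.1, 0.25, -0.7, 0.05, 0.2])
        got = ce.hc3_covariance(X, e)
        # brute force: explicit leverages and sandwich, element by element
        xtx_inv = np.linalg.inv(X.T @ X)
        H = X @ xtx_inv @ X.T
        meat = np.zeros((2, 2))
        for i in range(6):
            xi = X[i][:, None]
            meat += (e[i] ** 2 / (1 - H[i, i]) ** 2) * (xi @ xi.T)
        expected = xtx_inv @ meat @ xtx_inv
        assert np.abs(got - expected).max() < 1e-12

    def test_residual_scaling_homogeneity(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        e = rng.standard_normal(20)
        assert np.allclose(ce.hc3_covariance(X, 3.0 * e),
                           9.0 * ce.hc3_covariance(X, e), atol=1e-12)

    def test_matches_statsmodels_hc3(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        y = X @ [1.0, 0.5, -0.3] + rng.standard_normal(40) * (1 + 0.5 * np.abs(X[:, 1]))
        fit = sm.OLS(y, X).fit(cov_type="HC3")
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        got = ce.hc3_covariance(X, y - X @ beta)
        assert np.abs(got - fit.cov_params()).max() < 1e-8

    def test_homoskedastic_hc3_close_to_classical(self):
        rng = np.random.default_rng(3)
        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ [0.5, 1.0, -1.0] + rng.standard_normal(n)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ beta
        hc3_se = np.sqrt(np.diag(ce.hc3_covariance(X, e)))
        s2 = e @ e / (n - 3)
        ols_se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert np.abs(hc3_se / ols_se - 1).max() < 0.10

    def test_singular_design_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="singular|collinear"):
            ce.hc3_covariance(X, np.zeros(10))


class TestOutcomeModel:
    def test_noise_free_recovers_generating_coefficients(self):
        spec = OutcomeSpec(noise_sd=0.0, missing_rate=0.0)
        tab = simulate_outcome_table(outcome=spec, seed=4)
        fit = _fit_table(tab)
        expected = {"const": spec.d0, "age": spec.d1,
                    "bmi_sds_baseline": spec.d2, "spect": spec.d3,
                    "bmi_sds_baseline:spect": spec.d4}
        for term, value in expected.items():
            assert fit.params[term] == pytest.approx(value, abs=1e-8)

    def test_interaction_column_is_exact_product(self):
        tab = simulate_outcome_table(seed=5).dropna()
        X = _design_from_table(tab)
        prod = X["bmi_sds_baseline"] * X["spect"]
        assert np.abs(X["bmi_sds_baseline:spect"] - prod).max() < 1e-12

    def test_sign_recovery_at_paper_like_n(self):
        both_negative = 0
        for i in range(100):
            tab = simulate_outcome_table(seed=10_000 + i)
            fit = _fit_table(tab)
            both_negative += (fit.params["spect"] < 0
                              and fit.params["bmi_sds_baseline:spect"] < 0)
        assert both_negative >= 90

    def test_model_variants_have_expected_terms(self, default_cohort,
                                                default_fit):
        res = default_fit.subject_residual_maps()
        sc = ce.subject_enrichment_scores(
            res, default_cohort.atlas,
            subject_ids=list(default_cohort.clinical["subject_id"]))
        scores = sc.to_frame()
        gct = pd.Series(ce.global_mean_ct(default_cohort),
                        index=default_cohort.clinical["subject_id"])
        for model, terms in MODEL_TERMS.items():
            fit = ce.fit_outcome_model(default_cohort.clinical, scores, "SERT",
                                       model=model, global_ct=gct)
            assert list(fit.params.index) == ["const"] + terms

    def test_alt2_keeps_interaction_sign_in_noise_free_data(self):
        spec = OutcomeSpec(noise_sd=0.0, missing_rate=0.0)
        tab = simulate_outcome_table(outcome=spec, seed=6).dropna()
        X = _design_from_table(tab)
        rng = np.random.default_rng(7)
        X2 = X.copy()
        X2["global_ct"] = 2.5 + 0.05 * rng.standard_normal(len(X))
        e1 = ModeratedOutcomeModel().fit(X, tab["delta_bmi_sds"])
        e2 = ModeratedOutcomeModel().fit(X2, tab["delta_bmi_sds"])
        assert np.sign(e1.params_["bmi_sds_baseline:spect"]) == np.sign(
            e2.params_["bmi_sds_baseline:spect"])
        assert e2.params_["bmi_sds_baseline:spect"] == pytest.approx(
            e1.params_["bmi_sds_baseline:spect"], abs=1e-6)

    def test_unknown_model_and_missing_global_ct(self, default_cohort):
        with pytest.raises(ValueError, match="unknown model"):
            ce.fit_outcome_model(default_cohort.clinical, pd.DataFrame(),
                                 "SERT", model="alt9")


def _grid_scan_boundaries(fit, lo=-8.0, hi=2.0, step=1e-4, alpha=0.05):
    """Independent oracle: scan |t(w)| - t_crit sign changes on a dense grid."""
    b3 = fit.params["spect"]
    b4 = fit.params["bmi_sds_baseline:spect"]
    v33 = fit.cov.loc["spect", "spect"]
    v34 = fit.cov.loc["spect", "bmi_sds_baseline:spect"]
    v44 = fit.cov.loc["bmi_sds_baseline:spect", "bmi_sds_baseline:spect"]
    tc = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    w = np.arange(lo, hi + step, step)
    tval = (b3 + b4 * w) / np.sqrt(v33 + 2 * w * v34 + w ** 2 * v44)
    sig = np.abs(tval) > tc
    flips = np.flatnonzero(sig[:-1] != sig[1:])
    return w[flips] + step / 2


class TestJohnsonNeyman:
    def test_zero_interaction_with_significant_slope_covers_line(self):
        # exactly constant slope (no interaction, no residual): the whole
        # axis is significant
        rng = np.random.default_rng(8)
        n = 400
        w = rng.uniform(-6, 0, n)
        z = rng.standard_normal(n)
        y = 1.0 + 0.8 * z
        X = pd.DataFrame({"age": rng.uniform(12, 29, n), "bmi_sds_baseline": w,
                          "spect": z, "bmi_sds_baseline:spect": w * z})
        est = ModeratedOutcomeModel().fit(X, y)
        fit = OutcomeFit("main", "SERT", est, (w.min(), w.max()))
        jn = ce.johnson_neyman(fit)
        assert len(jn.regions) == 1
        assert jn.regions[0].lower == -np.inf
        assert jn.regions[0].upper == np.inf

    def test_null_simulation_rarely_finds_regions_in_range(self):
        empty_in_range = 0
        spec = OutcomeSpec(d3=0.0, d4=0.0)
        for i in range(100):
            tab = simulate_outcome_table(outcome=spec, seed=20_000 + i)
            fit = _fit_table(tab)
            jn = ce.johnson_neyman(fit)
            in_range = [r for r in jn.regions if not r.extrapolated]
            empty_in_range += not in_range
        assert empty_in_range >= 85

    def test_boundary_t_statistic_equals_critical_value(self):
        tab = simulate_outcome_table(seed=7)
        fit = _fit_table(tab)
        jn = ce.johnson_neyman(fit)
        b3 = fit.params["spect"]
        b4 = fit.params["bmi_sds_baseline:spect"]
        v33 = fit.cov.loc["spect", "spect"]
        v34 = fit.cov.loc["spect", "bmi_sds_baseline:spect"]
        v44 = fit.cov.loc["bmi_sds_baseline:spect", "bmi_sds_baseline:spect"]
        assert jn.boundaries  # the default effect produces finite boundaries
        for w in jn.boundaries:
            t = abs(b3 + b4 * w) / np.sqrt(v33 + 2 * w * v34 + w ** 2 * v44)
            assert t == pytest.approx(jn.t_crit, abs=1e-6)

    @pytest.mark.parametrize("seed", [7, 11, 23, 31])
    def test_closed_form_agrees_with_grid_scan(self, seed):
        tab = simulate_outcome_table(seed=seed)
        fit = _fit_table(tab)
        jn = ce.johnson_neyman(fit)
        expected = _grid_scan_boundaries(fit)
        got = [b for b in jn.boundaries if -8 <= b <= 2]
        assert len(got) == len(expected)
        for g, e in zip(sorted(got), sorted(expected)):
            assert abs(g - e) < 2e-4

    def test_two_disjoint_regions_like_severe_moderation(self):
        tab = simulate_outcome_table(seed=7)
        fit = _fit_table(tab)
        jn = ce.johnson_neyman(fit)
        assert len(jn.regions) == 2
        lo_region, hi_region = jn.regions
        assert lo_region.lower == -np.inf and hi_region.upper == np.inf
        assert lo_region.upper < hi_region.lower
        assert lo_region.slope_sign == 1 and hi_region.slope_sign == -1

    def test_jn_table_is_tidy(self):
        tab = simulate_outcome_table(seed=7)
        jn = ce.johnson_neyman(_fit_table(tab))
        frame = jn_table(jn)
        assert list(frame.columns) == ["moderator", "focal", "alpha", "t_crit",
                                       "lower", "upper", "slope_sign",
                                       "extrapolated"]
        assert len(frame) == len(jn.regions)


class TestSubsamples:
    def test_no_exclusion_filter_identical_to_main(self, default_cohort,
                                                   default_fit):
        res = default_fit.subject_residual_maps()
        sc = ce.subject_enrichment_scores(
            res, default_cohort.atlas,
            subject_ids=list(default_cohort.clinical["subject_id"]))
        scores = sc.to_frame()
        main = ce.fit_outcome_model(default_cohort.clinical, scores, "SERT")
        fits = ce.subsample_refit(default_cohort.clinical, scores, "SERT",
                                  filters={"everyone": lambda c: c["age"] > 0})
        assert np.allclose(fits["everyone"].params, main.params, atol=1e-12)

    def test_default_filters_recover_interaction_sign(self, default_cohort,
                                                      default_fit):
        res = default_fit.subject_residual_maps()
        sc = ce.subject_enrichment_scores(
            res, default_cohort.atlas,
            subject_ids=list(default_cohort.clinical["subject_id"]))
        scores = sc.to_frame()
        fits = ce.subsample_refit(default_cohort.clinical, scores, "SERT")
        assert set(fits) == {"restrictive-only", "no-comorbidity",
                             "no-antidepressant"}
        for name, fit in fits.items():
            assert fit.params["bmi_sds_baseline:spect"] < 0, name
            assert fit.n <= (default_cohort.clinical["group"] == "AN").sum()

    def test_empty_subset_raises(self, default_cohort):
        with pytest.raises(ValueError, match="empty"):
            ce.subsample_refit(default_cohort.clinical, pd.DataFrame(), "SERT",
                               filters={"none": lambda c: c["age"] < 0})
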