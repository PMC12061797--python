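"""Hurdle model: predictions, fitting, LRT, marginal means, metrics."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import qsmflora as qf
from qsmflora import constants as C
from qsmflora.branch_data import records_to_frame, trees_to_frame
from qsmflora.errors import DegenerateFitError, NestingError, SpecificationError
from qsmflora.hurdle import (
    PartFit,
    estimated_marginal_means,
    fit_hurdle,
    fit_metrics,
    likelihood_ratio_test,
    ztnb_mean,
)
from qsmflora.synthetic import SyntheticForestSpec


@pytest.fixture(scope="module")
def laplace_fit():
    """One mixed-effects hurdle fit on data with nested random intercepts."""
    spec = SyntheticForestSpec(n_trees=8, cutoffs_per_tree=6)
    records, trees, _ = qf.generate_branch_dataset(spec, seed=11)
    df, tdf = records_to_frame(records), trees_to_frame(trees)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_hurdle(df, tdf, random_effects=True, compute_se=False)
    return df, tdf, fit


class TestPredictions:
    def test_occurrence_probability_reference_values(self):
        # direct evaluation of the occurrence linear predictor
        p = qf.predict_occurrence_probability(20, 20, "out", "bot", C.REFERENCE_HURDLE)
        assert p == pytest.approx(expit(-2.85 + 2.16 * np.log(20) + 0.13 * 20), abs=1e-12)
        assert p == pytest.approx(0.998, abs=1e-3)
        p2 = qf.predict_occurrence_probability(3, 10, "in", "bot", C.REFERENCE_HURDLE)
        assert p2 == pytest.approx(expit(-2.85 + 2.16 * np.log(3) + 1.3 - 3.38), abs=1e-12)
        assert p2 == pytest.approx(0.072, abs=1e-3)

    def test_probability_monotone_in_diameter_and_saturates(self):
        D = np.array([3.0, 5, 10, 20, 30, 50, 80])
        p = qf.predict_occurrence_probability(D, 18, "out", "bot", C.REFERENCE_HURDLE)
        assert np.all(np.diff(p) > 0)
        assert p[D >= 25].min() > 0.99  # saturates above ~2 cm

    def test_conditional_count_reference_value(self):
        mu = np.exp(0.42 + 1.22 * np.log(10) - 0.06 * 20 + 0.04 * np.log(10) * 20)
        assert mu == pytest.approx(48.0, abs=0.01)
        m = qf.predict_conditional_count(10, 20, "out", "bot", C.REFERENCE_HURDLE)
        assert m == pytest.approx(ztnb_mean(mu, 1.5), rel=1e-12)
        assert m >= mu

    def test_ztnb_mean_limits(self):
        assert ztnb_mean(1e-14, 1.5) == pytest.approx(1.0)
        mu = 3.7
        assert ztnb_mean(mu, 1e8) == pytest.approx(mu / (1 - np.exp(-mu)), rel=1e-4)
        assert ztnb_mean(mu, 1.5) >= max(mu, 1.0)

    def test_combined_expectation_monotone_in_diameter(self):
        D = np.linspace(3, 30, 40)
        e = qf.predict_unconditional_count(D, 18, "out", "mid", C.REFERENCE_HURDLE)
        assert np.all(np.diff(e) > 0)

    def test_zero_crown_coefficients_make_position_irrelevant(self):
        occ = dataclasses.replace(
            C.OCCURRENCE_COEFS, layer_in=0.0, stratum_mid=0.0, stratum_top=0.0,
            in_mid=0.0, in_top=0.0,
        )
        ab = dataclasses.replace(
            C.ABUNDANCE_COEFS, layer_in=0.0, stratum_mid=0.0, stratum_top=0.0,
            in_mid=0.0, in_top=0.0,
        )
        coefs = dataclasses.replace(C.REFERENCE_HURDLE, occurrence=occ, abundance=ab)
        vals = {
            (lay, s): qf.predict_unconditional_count(10, 18, lay, s, coefs)
            for lay in ("in", "out")
            for s in ("bot", "mid", "top")
        }
        assert len({round(v, 12) for v in vals.values()}) == 1

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            qf.predict_occurrence_probability(-1, 10, "out", "bot", C.REFERENCE_HURDLE)
        with pytest.raises(ValueError):
            ztnb_mean(5.0, 0.0)


class TestFitting:
    def test_intercept_only_occurrence_matches_closed_form(self):
        rng = np.random.default_rng(1)
        n = 500
        y = (rng.uniform(size=n) < 0.6).astype(int) * (1 + rng.poisson(3, n))
        df = pd.DataFrame(
            {
                "tree_id": ["T1"] * (n // 2) + ["T2"] * (n - n // 2),
                "branch_id": [f"b{i}" for i in range(n)],
                "cutoff_diameter_mm": 10.0,
                "dbh_cm": 18.0,
                "stratum": "bot",
                "layer": "out",
                "flowers": y,
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_hurdle(df)
        # constant covariates: only the intercept chain is identified, and
        # the implied occurrence probability is the empirical nonzero rate
        X = np.array([1.0, np.log(10.0), 18.0, 0, 0, 0, 0, 0])
        eta = float(X @ fit.occurrence.params)
        assert eta == pytest.approx(logit((y > 0).mean()), abs=1e-5)

    def test_degenerate_outcomes_raise(self, small_frames):
        df, tdf = small_frames
        allpos = df.copy()
        allpos["flowers"] = 5
        with pytest.raises(DegenerateFitError):
            fit_hurdle(allpos, tdf)

    def test_fixed_fit_invariant_to_record_order(self, small_frames, fitted_fixed):
        df, tdf = small_frames
        shuffled = df.sample(frac=1.0, random_state=4)
        fit2 = fit_hurdle(shuffled, tdf)
        assert np.allclose(fit2.occurrence.params, fitted_fixed.occurrence.params, atol=1e-6)
        assert np.allclose(fit2.abundance.params, fitted_fixed.abundance.params, atol=1e-4)
        assert fit2.loglik == pytest.approx(fitted_fixed.loglik, abs=1e-4)

    def test_laplace_recovers_random_sds_and_single_tree_boundary(self, laplace_fit):
        df, tdf, fit = laplace_fit
        # abundance variance components are estimable on count data
        # (generating SDs are 0.3 at both levels, theta = 1.5)
        assert 0.03 < fit.abundance.sd_branch < 1.0
        assert 0.03 < fit.abundance.sd_tree < 1.0
        assert fit.abundance.theta == pytest.approx(1.5, abs=0.8)
        # single tree: tree-level SD reported at the boundary with a warning
        one = df[df["tree_id"] == df["tree_id"].iloc[0]]
        with pytest.warns(UserWarning):
            fit1 = fit_hurdle(one, tdf, random_effects=True, compute_se=False)
        assert fit1.abundance.sd_tree == 0.0


class TestBackwardSelection:
    def test_null_crown_effects_are_dropped_and_real_ones_kept(self, truth_no_re):
        # truth with no crown or interaction structure in either part
        occ = dataclasses.replace(
            C.OCCURRENCE_COEFS, layer_in=0.0, stratum_mid=0.0, stratum_top=0.0,
            in_mid=0.0, in_top=0.0,
        )
        truth = dataclasses.replace(truth_no_re, occurrence=occ)
        spec = SyntheticForestSpec(n_trees=25, cutoffs_per_tree=6, hurdle=truth)
        records, trees, _ = qf.generate_branch_dataset(spec, seed=77)
        from qsmflora.hurdle import backward_select

        df, tdf = records_to_frame(records), trees_to_frame(trees)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, dropped = backward_select(df, tdf, part="occurrence")
        assert "in_mid+in_top" in dropped  # null interaction removed
        assert "ln_diameter" in fit.param_names  # strong true effect kept
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_ab, dropped_ab = backward_select(df, tdf, part="abundance")
        # abundance truth retains its crown structure
        assert {"layer_in", "stratum_mid"} <= set(fit_ab.param_names)


class TestLikelihoodRatio:
    def test_identical_models_give_zero_statistic(self, fitted_fixed):
        res = likelihood_ratio_test(fitted_fixed.occurrence, fitted_fixed.occurrence)
        assert res.statistic == 0.0
        assert res.df == 0
        assert res.pvalue == 1.0

    def test_df_equals_dropped_parameter_count(self, fitted_fixed):
        occ = fitted_fixed.occurrence
        reduced = PartFit(
            part="occurrence",
            param_names=occ.param_names[:-2],
            params=occ.params[:-2],
            bse=occ.bse[:-2],
            cov=None,
            loglik=occ.loglik - 1.0,
            n_obs=occ.n_obs,
        )
        res = likelihood_ratio_test(occ, reduced)
        assert res.df == 2
        assert res.statistic == pytest.approx(2.0)
        with pytest.raises(NestingError):
            likelihood_ratio_test(reduced, occ)

    def test_type_i_error_rate_under_the_null(self):
        # drop a truly-null covariate; rejection rate should sit near alpha
        rng = np.random.default_rng(21)
        import statsmodels.api as sm

        rejections = 0
        B = 200
        for _ in range(B):
            n = 150
            x1 = rng.normal(size=n)
            x_null = rng.normal(size=n)
            p = expit(0.3 + 0.8 * x1)
            y = (rng.uniform(size=n) < p).astype(float)
            Xf = np.column_stack([np.ones(n), x1, x_null])
            Xr = Xf[:, :2]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                llf = sm.Logit(y, Xf).fit(disp=0).llf
                llr = sm.Logit(y, Xr).fit(disp=0).llf
            full = PartFit("occurrence", ["a", "b", "c"], np.zeros(3), np.zeros(3), None, llf, n)
            red = PartFit("occurrence", ["a", "b"], np.zeros(2), np.zeros(2), None, llr, n)
            if likelihood_ratio_test(full, red).pvalue < 0.05:
                rejections += 1
        assert 0.02 <= rejections / B <= 0.09


class TestMarginalMeans:
    def test_differences_equal_coefficients_without_interaction(self, fitted_fixed):
        occ = fitted_fixed.occurrence
        no_int = dataclasses.replace(
            occ,
            params=np.array([*occ.params[:6], 0.0, 0.0]),
            cov=np.eye(8) * 0.01,
        )
        means, comp = estimated_marginal_means(no_int, "layer")
        diff = float(
            means.set_index("level").loc["in", "emmean"]
            - means.set_index("level").loc["out", "emmean"]
        )
        assert diff == pytest.approx(no_int.params[3], abs=1e-10)

    def test_two_level_tukey_equals_unadjusted_z_test(self, fitted_fixed):
        from scipy import stats

        means, comp = estimated_marginal_means(fitted_fixed.abundance, "layer")
        row = comp.iloc[0]
        z = abs(row["estimate"]) / row["se"]
        assert row["p_tukey"] == pytest.approx(2 * stats.norm.sf(z), rel=1e-3)

    def test_outer_layer_exceeds_inner_with_significance(self, fitted_fixed):
        # generating truth has a strong negative inner-layer effect
        means, comp = estimated_marginal_means(fitted_fixed.abundance, "layer")
        m = means.set_index("level")["emmean"]
        assert m["out"] > m["in"]
        assert comp["p_tukey"].iloc[0] < 0.05

    def test_missing_factor_raises(self, fitted_fixed):
        with pytest.raises(SpecificationError):
            estimated_marginal_means(fitted_fixed.occurrence, "compass")


class TestMetrics:
    def test_rmse_at_least_mae_and_r2_in_range(self, fitted_fixed, small_frames):
        df, tdf = small_frames
        for part in (fitted_fixed.occurrence, fitted_fixed.abundance):
            m = fit_metrics(part, df, tdf)
            assert m.rmse_marginal >= m.mae_marginal
            assert 0.0 <= m.r2_marginal <= m.r2_conditional <= 1.0

    def test_conditional_r2_exceeds_marginal_with_random_effects(self, laplace_fit):
        df, tdf, fit = laplace_fit
        m = fit_metrics(fit.abundance, df, tdf)
        assert m.r2_conditional > m.r2_marginal
        assert m.mae_conditional <= m.mae_marginal

    def test_loocv_errors_exceed_in_sample(self, fitted_fixed, small_frames):
        df, tdf = small_frames
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_metrics(fitted_fixed.occurrence, df, tdf, loocv=True)
        assert m.mae_cv is not None
        assert m.mae_cv >= 0.8 * m.mae_marginal  # held-out error is no free lunch
        assert m.rmse_cv >= m.mae_cv
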