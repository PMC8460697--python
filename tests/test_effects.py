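"""Adjusted regression, inverse-probability weighting, and the
paternal-weight quantitative bias analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from artgrowth import GeneratorConfig, analysis_frame, generate_cohort
from artgrowth.effects import (PRE_PLUS_PREGNANCY, PRE_PREGNANCY,
                               CovariateSet, adjusted_effect, fit_weights,
                               paternal_weight_bias, weighted_effect)
from artgrowth.mice import chained_impute


def _simple_frame(n, seed, *, true_effect=2.0, censor=None, confounded=False):
    """w -> y; optional confounded assignment and censoring mechanism."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 1, n)
    if confounded:
        g = expit(0.8 * w)
        a = (rng.random(n) < g).astype(float)
    else:
        a = (rng.random(n) < 0.5).astype(float)
    y = true_effect * a + 2.0 * w + rng.normal(0, 1, n)
    df = pd.DataFrame({"art": a, "w": w, "y": y})
    df["y_observed"] = True
    if censor == "mcar":
        df.loc[rng.random(n) < 0.3, "y_observed"] = False
    elif censor == "informative":
        p_obs = expit(1.2 - 1.0 * a - 1.0 * w)
        df.loc[rng.random(n) > p_obs, "y_observed"] = False
    df.loc[~df.y_observed, "y"] = np.nan
    return df


W_ONLY = CovariateSet("w_only", ("w",))


class TestAdjustedEffect:
    def test_recovers_direct_effect(self, frame_large, large_single_visit_cohort):
        truth = large_single_visit_cohort.truth
        # the covariate-adjusted contrast targets the total effect
        est = adjusted_effect(frame_large, PRE_PREGNANCY)
        assert abs(est.estimate - truth["deltas"]["te"]) < 2 * est.se

    def test_permuted_treatment_is_null(self, frame_large):
        rng = np.random.default_rng(0)
        df = frame_large.copy()
        df["art"] = rng.permutation(df["art"].to_numpy())
        est = adjusted_effect(df, PRE_PREGNANCY)
        assert abs(est.estimate) < 2 * est.se

    def test_covariate_sets_agree_without_mediator_effects(self):
        """When mediators carry no effect, adding pregnancy covariates
        leaves the estimate essentially unchanged."""
        coefs = {k: 0.0 for k in GeneratorConfig().true_path_coefs}
        coefs["beta11"] = -2.0
        cfg = GeneratorConfig(true_path_coefs=coefs, seed=17, n_treated=150,
                              n_untreated=1350, visit_schedule=(72,))
        df = analysis_frame(generate_cohort(cfg), month=72)
        e1 = adjusted_effect(df, PRE_PREGNANCY)
        e2 = adjusted_effect(df, PRE_PLUS_PREGNANCY)
        assert abs(e1.estimate - e2.estimate) < 0.5 * e1.se

    def test_pooled_equals_complete_fit_when_nothing_missing(self, frame72):
        imp = chained_impute(frame72[["art", "y", "w" if "w" in frame72 else "mat_age"]],
                             m=3, seed=0)
        covs = CovariateSet("tiny", ("mat_age",))
        a = adjusted_effect(frame72, covs)
        b = adjusted_effect(frame72, covs, imputations=imp)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-10)

    def test_empty_arm_raises(self):
        df = _simple_frame(100, 0)
        df["art"] = 0.0
        with pytest.raises(ValueError):
            adjusted_effect(df, W_ONLY)


class TestWeights:
    def test_constant_propensity_gives_weight_two(self):
        df = _simple_frame(4000, 1)
        wf = fit_weights(df, CovariateSet("none", ()), truncate=None)
        assert np.allclose(wf.combined_weights, 2.0, atol=0.25)
        est_w = weighted_effect(df, wf)
        crude = (df.loc[df.art == 1, "y"].mean() - df.loc[df.art == 0, "y"].mean())
        assert est_w.estimate == pytest.approx(crude, abs=1e-6)

    def test_mcar_censoring_unbiased(self):
        reps = []
        for rep in range(100):
            df = _simple_frame(800, 100 + rep, censor="mcar")
            wf = fit_weights(df, W_ONLY)
            reps.append(weighted_effect(df, wf).estimate)
        mc_se = np.std(reps) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - 2.0) < 3 * mc_se

    def test_informative_censoring_bias_reduction(self):
        """Confounded assignment plus arm/covariate-dependent censoring:
        the weighted estimator shrinks the complete-case bias at least
        three-fold."""
        naive, weighted = [], []
        for rep in range(60):
            df = _simple_frame(2000, 500 + rep, censor="informative",
                               confounded=True)
            cc = df[df.y_observed]
            naive.append(cc.loc[cc.art == 1, "y"].mean()
                         - cc.loc[cc.art == 0, "y"].mean())
            wf = fit_weights(df, W_ONLY)
            weighted.append(weighted_effect(df, wf).estimate)
        bias_naive = abs(np.mean(naive) - 2.0)
        bias_w = abs(np.mean(weighted) - 2.0)
        assert bias_naive > 3 * bias_w


class TestWeightedEffect:
    def test_equal_weights_match_ols(self):
        import statsmodels.api as sm
        df = _simple_frame(300, 3)
        wf = fit_weights(df, CovariateSet("none", ()), truncate=None)
        wf.combined_weights[:] = 1.0
        est = weighted_effect(df, wf, covariates=("w",))
        X = np.column_stack([np.ones(len(df)), df.art, df.w])
        ols = sm.OLS(df.y, X).fit(cov_type="HC0")
        assert est.estimate == pytest.approx(float(ols.params.iloc[1]), abs=1e-10)
        assert est.se == pytest.approx(float(ols.bse.iloc[1]), abs=1e-10)

    def test_weight_scale_invariance(self):
        df = _simple_frame(300, 4)
        wf = fit_weights(df, W_ONLY, truncate=None)
        e1 = weighted_effect(df, wf)
        wf.combined_weights = wf.combined_weights * 2.0
        e2 = weighted_effect(df, wf)
        assert e1.estimate == pytest.approx(e2.estimate, abs=1e-10)
        assert e1.se == pytest.approx(e2.se, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Hand-coded weighted normal equations on a 10-row table."""
        df = _simple_frame(10, 5)
        wf = fit_weights(df, W_ONLY, truncate=None)
        est = weighted_effect(df, wf, covariates=("w",))
        X = np.column_stack([np.ones(10), df.art, df.w])
        Wm = np.diag(wf.combined_weights)
        beta = np.linalg.solve(X.T @ Wm @ X, X.T @ Wm @ df.y.to_numpy())
        assert est.estimate == pytest.approx(beta[1], abs=1e-10)


class TestPaternalWeightBias:
    def test_zero_delta_identity(self, frame_large):
        base = adjusted_effect(frame_large, PRE_PREGNANCY)
        traj = paternal_weight_bias(frame_large, [0.0])
        assert traj[0].estimate == pytest.approx(base.estimate, abs=1e-12)

    def test_linear_shift_matches_coefficient_oracle(self):
        """On a linear model, shifting treated-arm paternal weight by
        delta moves the treatment estimate by about -delta * (paternal
        weight outcome coefficient), per omitted/added-variable algebra at
        near-orthogonal design."""
        rng = np.random.default_rng(8)
        n = 20000
        a = (rng.random(n) < 0.5).astype(float)
        pw = rng.normal(75, 10, n)
        y = 1.0 * a + 0.05 * pw + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"art": a, "pat_weight": pw, "y": y})
        covs = CovariateSet("pw", ("pat_weight",))
        traj = paternal_weight_bias(df, [0.0, 10.0], covset=covs)
        slope = (traj[1].estimate - traj[0].estimate) / 10.0
        assert slope == pytest.approx(-0.05, abs=0.01)

    def test_irrelevant_covariate_invariance(self):
        rng = np.random.default_rng(9)
        n = 2000
        a = (rng.random(n) < 0.5).astype(float)
        pw = rng.normal(75, 10, n)
        w = rng.normal(0, 1, n)
        y = 1.0 * a + w + rng.normal(0, 1, n)   # paternal weight truly inert
        df = pd.DataFrame({"art": a, "pat_weight": pw, "w": w, "y": y})
        covs = CovariateSet("w_only", ("w",))    # pat_weight not in the model
        traj = paternal_weight_bias(df, [-20, 0, 20], covset=covs)
        ests = [t.estimate for t in traj]
        assert max(ests) - min(ests) < 1e-8
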