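"""Parametric g-computation mediation: oracles, identities, calibration,
and the negative-control design."""

import numpy as np
import pandas as pd
import pytest

from artgrowth import GeneratorConfig, analysis_frame, generate_cohort
from artgrowth.mediation import (MediationResult, closed_form_effects,
                                 fit_structural_system, gcompute_effects,
                                 mediation_over_visits,
                                 negative_control_mediation)
from artgrowth.synthetic import closed_form_deltas

CPG = "cpg_cg03904042"
CPGM = "cpgm_cg03904042"


def _cohort_frame(seed=2, n_treated=200, n_untreated=1800, **cfg_kw):
    cfg = GeneratorConfig(seed=seed, n_treated=n_treated,
                          n_untreated=n_untreated, visit_schedule=(72,),
                          **cfg_kw)
    c = generate_cohort(cfg)
    return analysis_frame(c, month=72), c.truth


class TestStructuralFit:
    def test_parameter_recovery(self):
        df, truth = _cohort_frame(seed=12, n_treated=400, n_untreated=4600)
        fit = fit_structural_system(df, CPG)
        b = truth["path_coefs"]
        # treatment coefficients per equation (FG, SBP, GA, CPG, Y)
        expect = [b["beta1"], b["beta2"], b["beta4"], b["beta7"], b["beta11"]]
        # rough SE scale: residual sd / sqrt(n_treated-ish)
        for j, (est, tr) in enumerate(zip(fit.treat_coefs, expect)):
            se = fit.resid_sds[j] / np.sqrt(400) * 2.5
            assert abs(est - tr) < 2 * se, f"equation {j}: {est} vs {tr}"

    def test_constant_treatment_errors(self):
        df, _ = _cohort_frame()
        df["art"] = 0.0
        with pytest.raises(ValueError):
            fit_structural_system(df, CPG)

    def test_pure_noise_confounder_is_harmless(self):
        df, _ = _cohort_frame(seed=13)
        fit0 = fit_structural_system(df, CPG)
        df2 = df.copy()
        df2["junk"] = np.random.default_rng(0).normal(size=len(df2))
        fit1 = fit_structural_system(df2, CPG,
                                     confounders=(*fit0.confounder_cols[:0],
                                                  *("mat_age", "mat_education",
                                                    "mat_ethnicity", "parity",
                                                    "mat_height", "mat_ppbmi",
                                                    "smoke_home", "mat_income",
                                                    "pat_height", "pat_weight",
                                                    "child_sex", "prs", "junk")))
        b15_0 = fit0.parent_coefs[4][3]
        b15_1 = fit1.parent_coefs[4][3]
        se = fit0.resid_sds[4] / np.sqrt(len(df)) * 5
        assert abs(b15_0 - b15_1) < 2 * se


class TestGcompute:
    def test_nie_matches_path_tracing_oracle(self):
        """g-computation NIE equals the closed-form linear path sum
        b15 * (b7 + b8*d_FG + b9*d_SBP + b10*d_GA) to 1e-10."""
        df, _ = _cohort_frame(seed=4)
        fit = fit_structural_system(df, CPG)
        oracle = closed_form_effects(fit)
        res = gcompute_effects(df, CPG, n_boot=5, seed=0)
        assert res.nie == pytest.approx(oracle["nie"], abs=1e-10)
        assert res.te == pytest.approx(oracle["te"], abs=1e-10)

    def test_severed_mediator_gives_exact_zero_nie(self):
        coefs = dict(GeneratorConfig().true_path_coefs)
        for k in ("beta7", "beta8", "beta9", "beta10"):
            coefs[k] = 0.0
        df, _ = _cohort_frame(seed=5, true_path_coefs=coefs)
        res = gcompute_effects(df, CPG, n_boot=5, seed=1)
        # fitted path coefs are not exactly zero, but the oracle identity
        # must still hold and the point NIE be near-null
        fit = fit_structural_system(df, CPG)
        oracle = closed_form_effects(fit)
        assert res.nie == pytest.approx(oracle["nie"], abs=1e-10)
        assert abs(res.nie) < 3 * res.nie_se

    def test_te_additivity_per_replicate(self):
        df, _ = _cohort_frame(seed=6)
        res = gcompute_effects(df, CPG, n_boot=30, seed=2)
        assert res.te == pytest.approx(res.nde + res.nie, abs=1e-10)

    def test_printed_proportions_mediated(self):
        r1 = MediationResult("height_cm", 72, te=-2.2, nde=-2.03, nie=-0.17,
                             te_se=0.6, nde_se=0.6, nie_se=0.07, n_boot=100)
        assert round(r1.prop_mediated, 1) == 7.7
        r2 = MediationResult("height_cm", 72, te=-2.9, nde=-2.76, nie=-0.14,
                             te_se=0.8, nde_se=0.8, nie_se=0.17, n_boot=100)
        assert round(r2.prop_mediated, 1) == 4.8

    def test_n_boot_validation(self):
        df, _ = _cohort_frame(seed=7)
        with pytest.raises(ValueError):
            gcompute_effects(df, CPG, n_boot=1)

    def test_stochastic_draw_mode_agrees_in_expectation(self):
        """Residual-draw propagation gives the same point estimates as
        mean propagation up to Monte-Carlo noise in a linear system."""
        df, _ = _cohort_frame(seed=8)
        mean_mode = gcompute_effects(df, CPG, n_boot=5, seed=3)
        draw_mode = gcompute_effects(df, CPG, n_boot=40, seed=3,
                                     stochastic_draws=True)
        assert abs(draw_mode.te - mean_mode.te) < 3 * draw_mode.te_se

    def test_bootstrap_se_stability(self):
        df, _ = _cohort_frame(seed=9, n_treated=100, n_untreated=900)
        a = gcompute_effects(df, CPG, n_boot=100, seed=4)
        b = gcompute_effects(df, CPG, n_boot=400, seed=5)
        assert abs(a.nie_se - b.nie_se) / b.nie_se < 0.25


class TestNegativeControl:
    def test_null_when_assumptions_hold(self):
        """No maternal-CpG effects anywhere: the negative-control NIE sits
        within 2 SE of zero."""
        df, _ = _cohort_frame(seed=10)
        res = negative_control_mediation(df, CPGM, n_boot=50, seed=6)
        assert abs(res.nie) < 2 * res.nie_se

    def test_planted_confounder_detected(self):
        """An unmeasured common cause of maternal CpG and outcome makes
        the negative-control NIE systematically nonzero."""
        nies, ses = [], []
        for rep in range(20):
            df, _ = _cohort_frame(seed=600 + rep, n_treated=120,
                                  n_untreated=1080,
                                  maternal_cpg_art_coef=-0.5,
                                  unmeasured_confounder_to_cpgm=1.0,
                                  unmeasured_confounder_to_y=3.0)
            r = negative_control_mediation(df, CPGM, n_boot=30, seed=rep)
            nies.append(r.nie)
            ses.append(r.nie_se)
        assert np.mean(np.abs(nies)) > 3 * np.mean(ses)

    def test_ordering_invariance_of_te_under_null(self):
        """With all structural coefficients zero, both equation orderings
        estimate the same (fitted) total effect."""
        coefs = {k: 0.0 for k in GeneratorConfig().true_path_coefs}
        df, _ = _cohort_frame(seed=11, true_path_coefs=coefs)
        fetal = gcompute_effects(df, CPG, n_boot=5, seed=7,
                                 ordering="fetal_cpg_last_mediator")
        # maternal ordering re-uses the same mediators but puts the
        # maternal CpG first; the TE is the same regression-standardized
        # contrast either way when no pathway carries signal
        maternal = gcompute_effects(df, CPGM, n_boot=5, seed=7,
                                    ordering="maternal_cpg_first_mediator")
        assert abs(fetal.te - maternal.te) < 2 * max(fetal.te_se, maternal.te_se)


class TestOverVisits:
    def test_single_visit_equals_direct_call(self, default_cohort):
        sub, vis = default_cohort.subjects, default_cohort.visits
        series = mediation_over_visits(sub, vis, CPG, "height_cm", [72],
                                       n_boot=10, seed=8)
        df = analysis_frame(default_cohort, month=72)
        # seeds are spawned per visit, so compare point estimates only
        direct = gcompute_effects(df, CPG, n_boot=2, seed=0)
        assert series[0].te == pytest.approx(direct.te, abs=1e-10)
        assert series[0].visit_month == 72

    def test_subcohort_restriction_on_homogeneous_population(self, default_cohort):
        sub, vis = default_cohort.subjects, default_cohort.visits
        full = mediation_over_visits(sub, vis, CPG, "height_cm", [72],
                                     n_boot=30, seed=9)[0]
        trial = mediation_over_visits(sub, vis, CPG, "height_cm", [72],
                                      subcohort="subfertile_plus_paternal",
                                      n_boot=30, seed=9)[0]
        assert abs(full.te - trial.te) < 2.5 * max(full.te_se, trial.te_se)
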