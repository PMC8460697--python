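"""Self-contained validation scenarios for the full pipeline.

Each function builds its own inputs (simulated under stated conditions or
taken from printed, self-contained numbers), runs the package's
estimators from scratch, and returns the summary quantities.  They back
both the validation test suite and the reproduction script.

Problem sizes are desk-scale: replicate-based checks use cohorts of a few
hundred to a few thousand subjects so a full run stays in the minutes
range on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .effects import (PRE_PREGNANCY, CovariateSet, adjusted_effect,
                      fit_weights, weighted_effect)
from .mediation import (MediationResult, closed_form_effects,
                        fit_structural_system, gcompute_effects,
                        negative_control_mediation)
from .superlearner import ctmle_ate, default_library
from .synthetic import (GeneratorConfig, analysis_frame, closed_form_deltas,
                        generate_cohort)

CPG = "cpg_cg03904042"
CPGM = "cpgm_cg03904042"

#: Structural truth used by the recovery scenarios: direct effect -2.0 cm,
#: methylation-to-outcome 0.5, treatment-to-methylation -0.3 SD.
RECOVERY_COEFS = dict(GeneratorConfig().true_path_coefs,
                      beta11=-2.0, beta15=0.5, beta7=-0.3)


def _single_visit_frame(seed, n_treated, n_untreated, coefs=None, **kw):
    cfg = GeneratorConfig(seed=seed, n_treated=n_treated,
                          n_untreated=n_untreated, visit_schedule=(72,),
                          true_path_coefs=coefs or dict(GeneratorConfig().true_path_coefs),
                          **kw)
    return analysis_frame(generate_cohort(cfg), month=72)


def mediation_oracle_gap(seed: int = 0, n: int = 2000) -> float:
    """Max |g-computation - closed-form path sum| over TE/NDE/NIE on one
    fixed simulated dataset."""
    df = _single_visit_frame(seed, n // 10, n - n // 10)
    fit = fit_structural_system(df, CPG)
    oracle = closed_form_effects(fit)
    res = gcompute_effects(df, CPG, n_boot=2, seed=seed)
    return max(abs(res.te - oracle["te"]), abs(res.nde - oracle["nde"]),
               abs(res.nie - oracle["nie"]))


def recovery_check(seed: int = 0, n_boot: int = 100, n_rep: int = 5) -> dict:
    """TE/NDE/NIE recovery against the generating coefficients on
    2000-subject cohorts.

    Each effect's error is expressed in bootstrap-SE units and averaged
    over ``n_rep`` independent cohorts (the mean |error|/SE of an
    unbiased, well-calibrated estimator concentrates near 0.8; a biased
    one drifts above 2)."""
    truth = closed_form_deltas(RECOVERY_COEFS)
    errs = {"te": [], "nde": [], "nie": []}
    last = None
    for rep in range(n_rep):
        df = _single_visit_frame(seed + 101 * rep, 200, 1800,
                                 coefs=RECOVERY_COEFS)
        last = gcompute_effects(df, CPG, n_boot=n_boot, seed=seed + 1 + rep)
        errs["te"].append(abs(last.te - truth["te"]) / last.te_se)
        errs["nde"].append(abs(last.nde - truth["nde"]) / last.nde_se)
        errs["nie"].append(abs(last.nie - truth["nie"]) / last.nie_se)
    return {
        "te": last.te, "nde": last.nde, "nie": last.nie,
        "te_truth": truth["te"], "nde_truth": truth["nde"], "nie_truth": truth["nie"],
        "te_err_se": float(np.mean(errs["te"])),
        "nde_err_se": float(np.mean(errs["nde"])),
        "nie_err_se": float(np.mean(errs["nie"])),
    }


def nie_coverage(seed: int = 0, n_rep: int = 200, n_treated: int = 60,
                 n_untreated: int = 440, n_boot: int = 50) -> float:
    """Fraction of replicates whose normal 95% CI for the NIE covers the
    generating value."""
    truth = closed_form_deltas(RECOVERY_COEFS)["nie"]
    covered = 0
    for rep in range(n_rep):
        df = _single_visit_frame(seed + rep, n_treated, n_untreated,
                                 coefs=RECOVERY_COEFS)
        r = gcompute_effects(df, CPG, n_boot=n_boot, seed=seed + 10_000 + rep)
        lo, hi = r.ci("nie")
        covered += lo <= truth <= hi
    return 100.0 * covered / n_rep


def null_calibration(seed: int = 0, n_rep: int = 100, n_boot: int = 40) -> float:
    """Severed treatment-to-methylation pathway: percent of replicates
    with |NIE| < 2 bootstrap SE."""
    coefs = dict(GeneratorConfig().true_path_coefs)
    for k in ("beta7", "beta8", "beta9", "beta10"):
        coefs[k] = 0.0
    ok = 0
    for rep in range(n_rep):
        df = _single_visit_frame(seed + rep, 80, 720, coefs=coefs)
        r = gcompute_effects(df, CPG, n_boot=n_boot, seed=seed + 20_000 + rep)
        ok += abs(r.nie) < 2 * r.nie_se
    return 100.0 * ok / n_rep


def negative_control_detection(seed: int = 0, n_rep: int = 20,
                               n_boot: int = 30) -> float:
    """Planted unmeasured common cause of maternal methylation and
    outcome: mean |NIE| over replicates in units of the mean bootstrap
    SE.  Values above 3 demonstrate the bias-detection function."""
    nies, ses = [], []
    for rep in range(n_rep):
        df = _single_visit_frame(seed + rep, 120, 1080,
                                 maternal_cpg_art_coef=-0.5,
                                 unmeasured_confounder_to_cpgm=1.0,
                                 unmeasured_confounder_to_y=3.0)
        r = negative_control_mediation(df, CPGM, n_boot=n_boot,
                                       seed=seed + 30_000 + rep)
        nies.append(abs(r.nie))
        ses.append(r.nie_se)
    return float(np.mean(nies) / np.mean(ses))


def double_robustness(seed: int = 0, n: int = 5000, n_rep: int = 10) -> dict:
    """Outcome model missing its quadratic term, true propensity
    covariates available to the greedy search: bias (in outcome-SD units)
    of C-TMLE vs the misspecified covariate-adjusted fit."""
    import statsmodels.api as sm
    true_effect = 2.0
    ctmle_est, ols_est, y_sds = [], [], []
    for rep in range(n_rep):
        rng = np.random.default_rng(seed + rep)
        w1 = rng.normal(0, 1, n)
        wsq = w1 ** 2
        g = expit(-1.0 + 0.7 * w1 + 0.7 * (wsq - 1.0))
        a = (rng.random(n) < g).astype(float)
        y = true_effect * a + w1 + 1.5 * wsq + rng.normal(0, 1, n)
        df = pd.DataFrame({"art": a, "w1": w1, "w1sq": wsq, "y": y})
        y_sds.append(y.std())
        # deliberately misspecified outcome model: quadratic omitted
        X = np.column_stack([np.ones(n), a, w1])
        fit = sm.OLS(y, X).fit()
        ols_est.append(float(fit.params[1]))
        q1 = fit.params[0] + fit.params[1] * 1.0 + fit.params[2] * w1
        q0 = fit.params[0] + fit.params[2] * w1
        res = ctmle_ate(df, "y", "art", ["w1", "w1sq"], seed=seed + rep,
                        q_predictions=(q1, q0))
        ctmle_est.append(res.ate)
    sd = float(np.mean(y_sds))
    return {"ctmle_bias_sd": abs(float(np.mean(ctmle_est)) - true_effect) / sd,
            "adjusted_bias_sd": abs(float(np.mean(ols_est)) - true_effect) / sd}


def ipw_bias_reduction(seed: int = 0, n_rep: int = 60, n: int = 2000) -> float:
    """Confounded assignment with arm- and covariate-dependent censoring:
    |bias| of the unweighted complete-case contrast divided by |bias| of
    the treatment-and-censoring weighted estimator."""
    true_effect = 2.0
    covs = CovariateSet("w_only", ("w",))
    naive, weighted = [], []
    for rep in range(n_rep):
        rng = np.random.default_rng(seed + rep)
        w = rng.normal(0, 1, n)
        a = (rng.random(n) < expit(0.8 * w)).astype(float)
        y = true_effect * a + 2.0 * w + rng.normal(0, 1, n)
        p_obs = expit(1.2 - 1.0 * a - 1.0 * w)
        obs = rng.random(n) < p_obs
        df = pd.DataFrame({"art": a, "w": w, "y": np.where(obs, y, np.nan),
                           "y_observed": obs})
        cc = df[df.y_observed]
        naive.append(cc.loc[cc.art == 1, "y"].mean()
                     - cc.loc[cc.art == 0, "y"].mean())
        wf = fit_weights(df, covs)
        weighted.append(weighted_effect(df, wf).estimate)
    bias_naive = abs(float(np.mean(naive)) - true_effect)
    bias_w = abs(float(np.mean(weighted)) - true_effect)
    return bias_naive / bias_w


def estimator_agreement(seed: int = 0) -> dict:
    """Randomized-treatment cohort: adjusted OLS, IPW, and C-TMLE (full
    ensemble library) on the same data; maximum pairwise disagreement in
    units of the larger SE of each pair."""
    cfg = GeneratorConfig(seed=seed, n_treated=150, n_untreated=1350,
                          visit_schedule=(72,), treatment_model={})
    df = analysis_frame(generate_cohort(cfg), month=72)
    adj = adjusted_effect(df, PRE_PREGNANCY)
    df_w = df.assign(y_observed=True)
    wf = fit_weights(df_w, PRE_PREGNANCY)
    ipw = weighted_effect(df_w, wf)
    ct = ctmle_ate(df, "y", "art", list(PRE_PREGNANCY.variables),
                   library=default_library(), seed=seed)
    ests = {"adjusted": (adj.estimate, adj.se), "ipw": (ipw.estimate, ipw.se),
            "ctmle": (ct.ate, ct.se)}
    worst = 0.0
    pairs = [("adjusted", "ipw"), ("adjusted", "ctmle"), ("ipw", "ctmle")]
    for p, q in pairs:
        d = abs(ests[p][0] - ests[q][0]) / max(ests[p][1], ests[q][1])
        worst = max(worst, d)
    return {**{f"{k}_est": v[0] for k, v in ests.items()},
            **{f"{k}_se": v[1] for k, v in ests.items()},
            "max_disagreement_se": worst}
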