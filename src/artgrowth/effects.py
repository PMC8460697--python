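"""Covariate-adjusted and inverse-probability-weighted treatment effects.

Two of the complementary estimation strategies for the treated-vs-control
contrast live here: multivariable linear regression on (optionally
multiply-imputed) covariates, and weighting by the inverse probability of
treatment and of remaining uncensored, fit in a complete-case setting.
A quantitative bias analysis for paternal-weight measurement error
re-estimates the adjusted effect after shifting treated-arm paternal
weight across a grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .mice import ImputationSet, pool_rubin
from .measures import percent_difference

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateSet", "EffectEstimate", "WeightFit",
    "PRE_PREGNANCY", "PRE_PLUS_PREGNANCY",
    "adjusted_effect", "fit_weights", "weighted_effect",
    "paternal_weight_bias", "design_matrix",
]


@dataclass(frozen=True)
class CovariateSet:
    name: str
    variables: tuple[str, ...]


#: Pre-conception confounders: parental sociodemographics, anthropometry
#: and comorbidity history, child sex and polygenic risk score.
PRE_PREGNANCY = CovariateSet("pre_pregnancy", (
    "mat_age", "mat_education", "mat_ethnicity", "mat_income", "mat_height",
    "mat_ppbmi", "parity", "smoke_home", "pat_age", "pat_height", "pat_weight",
    "pat_diabetes", "pat_htn", "child_sex", "prs",
))

#: Extended set adding pregnancy-course covariates (glucose measures,
#: elevated blood pressure in pregnancy, gestational age at delivery).
PRE_PLUS_PREGNANCY = CovariateSet("pre_plus_pregnancy", PRE_PREGNANCY.variables + (
    "fg", "ogtt2h", "preg_htn", "ga_weeks",
))


@dataclass
class EffectEstimate:
    outcome: str
    visit_month: int | None
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    model_tag: str
    transform: str = "identity"
    p_value: float | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


@dataclass
class WeightFit:
    """Inverse-probability weights for treatment and censoring."""

    index: pd.Index                  # rows of the complete-case frame
    treatment_probs: np.ndarray      # g(W) on complete cases
    censor_probs: np.ndarray         # P(uncensored | A, W)
    combined_weights: np.ndarray     # aligned to `index`
    truncation_bounds: tuple[float, float] | None


def design_matrix(df: pd.DataFrame, covariates: tuple[str, ...],
                  include_treatment: bool = True) -> pd.DataFrame:
    """Model design: constant, treatment indicator first, then covariates
    with categorical columns one-hot encoded (first level dropped)."""
    cols = [c for c in covariates if c in df.columns]
    if cols:
        X = pd.get_dummies(df[cols], drop_first=True, dtype=float).astype(float)
    else:
        X = pd.DataFrame(index=df.index)
    if include_treatment:
        X.insert(0, "art", df["art"].astype(float))
    X.insert(0, "const", 1.0)
    return X


def _ols_art(df: pd.DataFrame, covariates: tuple[str, ...], outcome: str,
             log_outcome: bool) -> tuple[float, float, int]:
    sub = df.dropna(subset=[outcome, *[c for c in covariates if c in df.columns]])
    y = sub[outcome].to_numpy(dtype=float)
    if log_outcome:
        if (y <= 0).any():
            raise ValueError("log-scale outcome requires positive values")
        y = np.log(y)
    for arm in (0, 1):
        if ((sub["art"] == arm)).sum() == 0:
            raise ValueError(f"no observed outcomes in arm {arm} for {outcome!r}")
    X = design_matrix(sub, covariates)
    fit = sm.OLS(y, X).fit()
    return float(fit.params["art"]), float(fit.bse["art"]), len(sub)


def adjusted_effect(data: pd.DataFrame, covset: CovariateSet,
                    imputations: ImputationSet | None = None,
                    outcome: str = "y", visit_month: int | None = None,
                    log_outcome: bool = False) -> EffectEstimate:
    """Covariate-adjusted treated-vs-control difference by OLS.

    With an :class:`ImputationSet`, the model is fit once per completed
    dataset and the treatment coefficient pooled by Rubin's rules; without
    one the fit is on the supplied (complete) data.  Log-scale outcomes
    are reported as percent differences, with the CI endpoints transformed
    monotonically.
    """
    if imputations is not None:
        fits = []
        n = 0
        for df in imputations.datasets:
            est, se, n = _ols_art(df, covset.variables, outcome, log_outcome)
            fits.append((est, se))
        pooled = pool_rubin(fits, label=f"art:{outcome}")
        est, se = pooled.estimate, pooled.se
        lo, hi = pooled.ci()
        tag = f"adjusted+{covset.name}+mice{imputations.m}"
    else:
        est, se, n = _ols_art(data, covset.variables, outcome, log_outcome)
        lo, hi = est - 1.96 * se, est + 1.96 * se
        tag = f"adjusted+{covset.name}"
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    if log_outcome:
        est_pct, (lo, hi) = percent_difference(est, (lo, hi))
        return EffectEstimate(outcome, visit_month, float(est_pct),
                             se=float(abs(hi - lo) / (2 * 1.96)),
                             ci_low=float(lo), ci_high=float(hi), n=n,
                             model_tag=tag, transform="percent_difference",
                             p_value=float(p))
    return EffectEstimate(outcome, visit_month, est, se, float(lo), float(hi),
                          n=n, model_tag=tag, p_value=float(p))


def _fit_logistic(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Predicted probabilities from a multivariable logistic regression."""
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return np.asarray(res.predict(X), dtype=float)
    except Exception:  # separation etc. — fall back to a ridge-stabilized fit
        res = sm.Logit(y, X).fit_regularized(alpha=1e-4, disp=0)
        return np.asarray(res.predict(X), dtype=float)


def fit_weights(data: pd.DataFrame, covset: CovariateSet,
                censor_col: str = "y_observed",
                truncate: tuple[float, float] | None = (1.0, 99.0),
                positivity_clip: float = 1e-3,
                positivity_error_frac: float = 0.05) -> WeightFit:
    """Inverse-probability-of-treatment-and-censoring weights.

    Fit in a complete-case setting (rows with all covariates present):
    (1) a logistic model for treatment on the covariates gives g(W) and
    the weight A/g + (1-A)/(1-g); (2) a logistic model for remaining
    uncensored (outcome observed) on treatment plus the covariates gives
    1/P(uncensored | A, W).  The combined weight is their product,
    optionally symmetric-percentile truncated.
    """
    covs = [c for c in covset.variables if c in data.columns]
    cc = data.dropna(subset=covs)
    a = cc["art"].to_numpy(dtype=float)
    Xg = design_matrix(cc, tuple(covs), include_treatment=False)
    g = _fit_logistic(Xg, a)
    extreme = (g < positivity_clip) | (g > 1 - positivity_clip)
    if extreme.mean() > positivity_error_frac:
        raise ValueError(
            f"{100 * extreme.mean():.1f}% of fitted treatment probabilities "
            f"lie outside [{positivity_clip}, {1 - positivity_clip}] "
            f"(range [{g.min():.2e}, {g.max():.2e}]): positivity violated")
    if extreme.any():
        logger.warning("IPW: clipping %d near-degenerate treatment "
                       "probabilities to [%g, %g]", int(extreme.sum()),
                       positivity_clip, 1 - positivity_clip)
        g = np.clip(g, positivity_clip, 1 - positivity_clip)
    tx_w = a / g + (1 - a) / (1 - g)

    if censor_col in cc.columns and cc[censor_col].astype(bool).nunique() > 1:
        obs = cc[censor_col].astype(bool).to_numpy().astype(float)
        Xc = design_matrix(cc, tuple(covs), include_treatment=True)
        p_obs = _fit_logistic(Xc, obs)
        p_obs = np.clip(p_obs, 1e-3, 1.0)
    else:
        p_obs = np.ones(len(cc))
    w = tx_w / p_obs
    bounds = None
    if truncate is not None:
        lo, hi = np.percentile(w, truncate)
        w = np.clip(w, lo, hi)
        bounds = (float(lo), float(hi))
    logger.info("IPW: n=%d, weight range [%.3g, %.3g]%s", len(cc), w.min(), w.max(),
                f", truncated to {bounds}" if bounds else "")
    return WeightFit(index=cc.index, treatment_probs=g, censor_probs=p_obs,
                     combined_weights=w, truncation_bounds=bounds)


def weighted_effect(data: pd.DataFrame, weights: WeightFit,
                    outcome: str = "y", visit_month: int | None = None,
                    covariates: tuple[str, ...] = (),
                    log_outcome: bool = False) -> EffectEstimate:
    """Weighted least squares with robust (sandwich) standard errors.

    By default the weighted model is treatment-only (the weights carry the
    standardization); covariates may be added for a doubly adjusted fit.
    """
    sub = data.loc[weights.index]
    keep = sub[outcome].notna().to_numpy()
    sub = sub[keep]
    w = weights.combined_weights[keep]
    if len(sub) != len(w):
        raise ValueError("weights misaligned with data rows")
    y = sub[outcome].to_numpy(dtype=float)
    if log_outcome:
        y = np.log(y)
    X = design_matrix(sub, covariates)
    fit = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    est, se = float(fit.params["art"]), float(fit.bse["art"])
    lo, hi = est - 1.96 * se, est + 1.96 * se
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    if log_outcome:
        est, (lo, hi) = percent_difference(est, (lo, hi))
        return EffectEstimate(outcome, visit_month, float(est),
                              float(abs(hi - lo) / (2 * 1.96)), float(lo), float(hi),
                              n=len(sub), model_tag="ipw",
                              transform="percent_difference", p_value=float(p))
    return EffectEstimate(outcome, visit_month, est, se, lo, hi, n=len(sub),
                          model_tag="ipw", p_value=float(p))


def paternal_weight_bias(data: pd.DataFrame, delta_kg_grid,
                         covset: CovariateSet = PRE_PREGNANCY,
                         outcome: str = "y") -> list[EffectEstimate]:
    """Quantitative bias analysis for paternal-weight measurement error.

    For each delta, paternal weight in the treated arm is shifted by
    +delta kg (emulating differential error between pre-conception truth
    and the post-delivery measurement) and the adjusted effect refit.
    """
    out = []
    for delta in delta_kg_grid:
        shifted = data.copy()
        mask = shifted["art"].astype(bool)
        shifted.loc[mask, "pat_weight"] = shifted.loc[mask, "pat_weight"] + float(delta)
        est = adjusted_effect(shifted, covset, outcome=outcome)
        est.model_tag = f"paternal_bias(delta={delta:+g}kg)"
        out.append(est)
    return out
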