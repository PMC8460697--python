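"""Parametric g-computation mediation with bootstrap inference.

A system of linear structural equations links treatment (ART
conception), the pregnancy mediators (fasting glucose FG, pregnancy
systolic blood pressure SBP, gestational age GA), a methylation residual
(CPG), and the child outcome Y, each adjusted for a shared confounder
vector:

    FG  = b1*A + G1'W + a1
    SBP = b2*A + b3*FG + G2'W + a2
    GA  = b4*A + b5*FG + b6*SBP + G3'W + a3
    CPG = b7*A + b8*FG + b9*SBP + b10*GA + G4'W + a4
    Y   = b11*A + b12*FG + b13*SBP + b14*GA + b15*CPG + G5'W + a5

Counterfactual outcomes are obtained by propagating interventions through
the fitted chain (mean propagation by default; residual draws behind a
flag).  The total effect (TE) contrasts assigning everyone to treatment
vs control; the natural direct effect (NDE) repeats the treated
propagation but holds the methylation mediator at the level each subject
would have under control; the natural indirect effect is NIE = TE - NDE.
Standard errors come from refitting the system in bootstrap resamples.

The negative-control variant swaps in maternal mid-pregnancy methylation
as the *first* mediator (it precedes the pregnancy course):

    CPG_M = b1*A + ...;  FG = b2*A + b3*CPG_M + ...;  ...

Under the fetal-imprinting hypothesis and no unmeasured confounding its
NIE should be null; a systematically nonzero estimate flags residual
confounding or a direct maternal-epigenome effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emulation import ArmRule, emulated_trial
from .synthetic import analysis_frame

logger = logging.getLogger(__name__)

__all__ = [
    "StructuralModelFit", "MediationResult", "MEDIATION_CONFOUNDERS",
    "fit_structural_system", "gcompute_effects", "closed_form_effects",
    "negative_control_mediation", "mediation_over_visits",
]

#: Shared confounder vector for every equation of the system.
MEDIATION_CONFOUNDERS = (
    "mat_age", "mat_education", "mat_ethnicity", "parity", "mat_height",
    "mat_ppbmi", "smoke_home", "mat_income", "pat_height", "pat_weight",
    "child_sex", "prs",
)


class SingularSystemError(np.linalg.LinAlgError):
    pass


@dataclass
class StructuralModelFit:
    """Fitted coefficients of the equation system.

    ``mediators`` lists mediator columns in causal order; equation ``j``
    regresses mediator j on treatment, mediators 0..j-1 and the
    confounders.  The final equation is the outcome on treatment, all
    mediators and the confounders.  ``mediator_of_interest`` is the one
    held fixed for the natural direct effect.
    """

    ordering: str
    treatment: str
    mediators: tuple[str, ...]
    mediator_of_interest: str
    outcome: str
    confounder_cols: tuple[str, ...]          # encoded design columns
    treat_coefs: np.ndarray                   # per equation (k mediators + outcome)
    parent_coefs: list[np.ndarray]            # eq j: coefs on mediators < j
    conf_coefs: np.ndarray                    # (k+1) x p
    intercepts: np.ndarray
    resid_sds: np.ndarray

    @property
    def moi_index(self) -> int:
        return self.mediators.index(self.mediator_of_interest)


@dataclass
class MediationResult:
    outcome: str
    visit_month: int | None
    te: float
    nde: float
    nie: float
    te_se: float
    nde_se: float
    nie_se: float
    n_boot: int
    n_dropped: int = 0
    point_from: str = "original_sample"

    @property
    def prop_mediated(self) -> float:
        """Percent of the total effect operating through the mediator of
        interest: 100 * NIE / TE."""
        return 100.0 * self.nie / self.te

    def ci(self, which: str = "nie", level: float = 0.95):
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        est = getattr(self, which)
        se = getattr(self, f"{which}_se")
        return est - z * se, est + z * se


def _conf_design(data: pd.DataFrame, confounders: tuple[str, ...],
                 ) -> tuple[np.ndarray, tuple[str, ...]]:
    X = pd.get_dummies(data[list(confounders)], drop_first=True, dtype=float)
    return X.to_numpy(dtype=float), tuple(X.columns)


def _check_rank(D: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        kept, aliased = [], []
        for j in range(D.shape[1]):
            if np.linalg.matrix_rank(D[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise SingularSystemError(f"singular structural design; aliased columns: {aliased}")


def _fit_equations(A: np.ndarray, M: np.ndarray, y: np.ndarray, Xc: np.ndarray,
                   check: bool, names: list[str]):
    """Sequential least squares for the k mediator equations + outcome."""
    n, k = M.shape
    treat = np.empty(k + 1)
    parents: list[np.ndarray] = []
    conf = np.empty((k + 1, Xc.shape[1]))
    icept = np.empty(k + 1)
    sds = np.empty(k + 1)
    ones = np.ones((n, 1))
    for j in range(k + 1):
        target = M[:, j] if j < k else y
        D = np.column_stack([ones, A[:, None], M[:, :min(j, k)], Xc])
        if check and j == k:
            _check_rank(D, ["const", "treatment", *list(names[:k]), *names[k:]])
        coef, _, rank, _ = np.linalg.lstsq(D, target, rcond=None)
        if rank < D.shape[1]:
            raise SingularSystemError("rank-deficient design in bootstrap refit")
        icept[j] = coef[0]
        treat[j] = coef[1]
        parents.append(coef[2:2 + min(j, k)].copy())
        conf[j] = coef[2 + min(j, k):]
        resid = target - D @ coef
        sds[j] = float(np.sqrt(np.maximum(resid @ resid, 0) / max(n - D.shape[1], 1)))
    return treat, parents, conf, icept, sds


def fit_structural_system(data: pd.DataFrame, cpg_col: str,
                          confounders: tuple[str, ...] = MEDIATION_CONFOUNDERS,
                          ordering: str = "fetal_cpg_last_mediator",
                          outcome: str = "y", treatment: str = "art",
                          ) -> StructuralModelFit:
    """Fit the full equation system by least squares.

    ``ordering`` selects the causal position of the methylation mediator:
    ``fetal_cpg_last_mediator`` places the (fetal cord) CpG after the
    pregnancy mediators; ``maternal_cpg_first_mediator`` places the
    (maternal blood) CpG before them, the negative-control layout.
    """
    if ordering == "fetal_cpg_last_mediator":
        mediators = ("fg", "sbp_preg", "ga_weeks", cpg_col)
    elif ordering == "maternal_cpg_first_mediator":
        mediators = (cpg_col, "fg", "sbp_preg", "ga_weeks")
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    sub = data.dropna(subset=[treatment, outcome, *mediators, *confounders])
    A = sub[treatment].to_numpy(dtype=float)
    if len(np.unique(A)) < 2:
        raise ValueError("treatment column is constant; system inestimable")
    M = sub[list(mediators)].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    Xc, conf_cols = _conf_design(sub, confounders)
    names = [*mediators, *conf_cols]
    treat, parents, conf, icept, sds = _fit_equations(A, M, y, Xc, True, names)
    return StructuralModelFit(
        ordering=ordering, treatment=treatment, mediators=mediators,
        mediator_of_interest=cpg_col, outcome=outcome,
        confounder_cols=conf_cols, treat_coefs=treat, parent_coefs=parents,
        conf_coefs=conf, intercepts=icept, resid_sds=sds)


def _propagate(treat, parents, conf, icept, sds, Xc, a: float,
               force_moi: np.ndarray | None, moi_index: int,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Counterfactual propagation through the chain at treatment ``a``.

    ``force_moi`` overrides the mediator-of-interest with supplied values
    (its own equation is skipped; downstream equations see the forced
    values).  Mean propagation unless an RNG is given, in which case
    residuals are drawn per equation.
    """
    n = Xc.shape[0]
    k = len(parents) - 1
    Mhat = np.empty((n, k))
    for j in range(k):
        if force_moi is not None and j == moi_index:
            Mhat[:, j] = force_moi
            continue
        v = icept[j] + treat[j] * a + Xc @ conf[j]
        if j > 0:
            v = v + Mhat[:, :j] @ parents[j]
        if rng is not None:
            v = v + rng.normal(0, sds[j], n)
        Mhat[:, j] = v
    yhat = icept[k] + treat[k] * a + Mhat @ parents[k] + Xc @ conf[k]
    if rng is not None:
        yhat = yhat + rng.normal(0, sds[k], n)
    return yhat


def _effects_from_fit(treat, parents, conf, icept, sds, Xc, moi_index,
                      rng=None) -> tuple[float, float, float]:
    n = Xc.shape[0]
    k = len(parents) - 1
    # mediator-of-interest level under control, for each subject
    M0 = np.empty((n, k))
    for j in range(k):
        v = icept[j] + Xc @ conf[j]
        if j > 0:
            v = v + M0[:, :j] @ parents[j]
        M0[:, j] = v
    moi_control = M0[:, moi_index]
    y1 = _propagate(treat, parents, conf, icept, sds, Xc, 1.0, None, moi_index, rng)
    y0 = _propagate(treat, parents, conf, icept, sds, Xc, 0.0, None, moi_index, rng)
    y1_fixed = _propagate(treat, parents, conf, icept, sds, Xc, 1.0,
                          moi_control, moi_index, rng)
    te = float(np.mean(y1 - y0))
    nde = float(np.mean(y1_fixed - y0))
    return te, nde, te - nde


def closed_form_effects(fit: StructuralModelFit) -> dict[str, float]:
    """Path-tracing TE/NDE/NIE for the all-linear system.

    Forward recursion gives each mediator's per-unit treatment response
    d_j = b_j^A + sum_{i<j} b_{j,i} d_i; backward recursion gives the
    outcome sensitivity s_j = b_Y,j + sum_{l>j} b_{l,j} s_l.  Then
    TE = b_Y^A + sum_j b_Y,j d_j and NIE = s_m d_m for the mediator of
    interest m.
    """
    k = len(fit.mediators)
    d = np.zeros(k)
    for j in range(k):
        d[j] = fit.treat_coefs[j] + (fit.parent_coefs[j] @ d[:j] if j else 0.0)
    s = np.zeros(k)
    b_y = fit.parent_coefs[k]
    for j in reversed(range(k)):
        s[j] = b_y[j] + sum(fit.parent_coefs[l][j] * s[l] for l in range(j + 1, k))
    te = float(fit.treat_coefs[k] + b_y @ d)
    nie = float(s[fit.moi_index] * d[fit.moi_index])
    return {"te": te, "nde": te - nie, "nie": nie,
            "mediator_deltas": d, "outcome_sensitivities": s}


def gcompute_effects(data: pd.DataFrame, cpg_col: str,
                     confounders: tuple[str, ...] = MEDIATION_CONFOUNDERS,
                     ordering: str = "fetal_cpg_last_mediator",
                     outcome: str = "y", treatment: str = "art",
                     n_boot: int = 100, seed: int = 0,
                     stochastic_draws: bool = False,
                     point_from_bootstrap_mean: bool = False,
                     visit_month: int | None = None) -> MediationResult:
    """Monte-Carlo g-computation of TE, NDE and NIE.

    The system is fit on the full sample for the point estimates and
    refit in ``n_boot`` with-replacement resamples; the SD of each effect
    across replicates is its standard error.  Replicates with singular
    refits are dropped (counted).  Within every replicate TE = NDE + NIE
    holds by construction.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    fit = fit_structural_system(data, cpg_col, confounders, ordering,
                                outcome, treatment)
    sub = data.dropna(subset=[treatment, outcome, *fit.mediators, *confounders])
    A = sub[treatment].to_numpy(dtype=float)
    M = sub[list(fit.mediators)].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    Xc, _ = _conf_design(sub, confounders)
    names = [*fit.mediators, *fit.confounder_cols]
    moi = fit.moi_index

    rng = np.random.default_rng(seed)
    draw_rng = rng if stochastic_draws else None
    point = _effects_from_fit(fit.treat_coefs, fit.parent_coefs, fit.conf_coefs,
                              fit.intercepts, fit.resid_sds, Xc, moi, draw_rng)

    n = len(y)
    reps = np.empty((n_boot, 3))
    dropped = 0
    for bidx in range(n_boot):
        rows = rng.integers(0, n, n)
        try:
            tr, pa, cf, ic, sd = _fit_equations(A[rows], M[rows], y[rows],
                                                Xc[rows], False, names)
            reps[bidx] = _effects_from_fit(tr, pa, cf, ic, sd, Xc[rows], moi,
                                           rng if stochastic_draws else None)
        except np.linalg.LinAlgError:
            reps[bidx] = np.nan
            dropped += 1
    if dropped:
        logger.warning("g-computation: %d/%d bootstrap replicate(s) dropped "
                       "(singular refit)", dropped, n_boot)
    ok = ~np.isnan(reps[:, 0])
    ses = reps[ok].std(axis=0, ddof=1)
    if point_from_bootstrap_mean:
        point = tuple(reps[ok].mean(axis=0))
        tag = "bootstrap_mean"
    else:
        tag = "original_sample"
    return MediationResult(
        outcome=outcome, visit_month=visit_month,
        te=point[0], nde=point[1], nie=point[2],
        te_se=float(ses[0]), nde_se=float(ses[1]), nie_se=float(ses[2]),
        n_boot=int(ok.sum()), n_dropped=dropped, point_from=tag)


def negative_control_mediation(data: pd.DataFrame, maternal_cpg_col: str,
                               confounders: tuple[str, ...] = MEDIATION_CONFOUNDERS,
                               n_boot: int = 100, seed: int = 0,
                               **kwargs) -> MediationResult:
    """The mediation engine with maternal mid-pregnancy methylation as the
    first mediator.  Under the fetal-imprinting hypothesis and no
    unmeasured confounding the NIE is null; a clearly nonzero NIE flags
    residual confounding or a direct maternal-epigenome effect."""
    return gcompute_effects(data, maternal_cpg_col, confounders,
                            ordering="maternal_cpg_first_mediator",
                            n_boot=n_boot, seed=seed, **kwargs)


def mediation_over_visits(subjects: pd.DataFrame, visits: pd.DataFrame,
                          cpg_col: str, outcome: str, visit_list,
                          subcohort: ArmRule | str | None = None,
                          confounders: tuple[str, ...] = MEDIATION_CONFOUNDERS,
                          n_boot: int = 100, seed: int = 0,
                          **kwargs) -> list[MediationResult]:
    """Run the mediation engine at each visit, optionally restricted to
    the emulated-trial arms (treated plus a comparison-arm rule)."""
    frame_source = emulated_trial(subjects, subcohort) if subcohort is not None else subjects
    results = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(list(visit_list)))]
    for month, s in zip(visit_list, child_seeds):
        df = analysis_frame(frame_source, visits, outcome=outcome, month=month)
        if df["art"].sum() == 0 or len(df) == 0:
            logger.warning("visit %s: no treated observations; skipped", month)
            continue
        res = gcompute_effects(df, cpg_col, confounders, outcome="y",
                               n_boot=n_boot, seed=s, visit_month=month, **kwargs)
        res.outcome = outcome
        results.append(res)
    return results
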