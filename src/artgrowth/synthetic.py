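"""Synthetic mother-father-child cohorts with a known causal structure.

The generator emulates the statistical skeleton of a two-arm observational
birth cohort in which a small group of children conceived by assisted
reproduction (ART) is followed alongside a much larger spontaneously
conceiving group: confounded treatment assignment, subfertility-indicator
flags, pregnancy mediators (fasting glucose, systolic blood pressure,
gestational age), standardized CpG methylation residuals for fetal and
maternal tissue, and a 16-visit longitudinal anthropometry schedule with
missing-at-random covariates and monotone dropout.

Mediators, methylation and outcomes are simulated sequentially through a
linear structural equation system

    FG   = b1*A + G1'W + a1 + e1
    SBP  = b2*A + b3*FG + G2'W + a2 + e2
    GA   = b4*A + b5*FG + b6*SBP + G3'W + a3 + e3
    CPG  = b7*A + b8*FG + b9*SBP + b10*GA + G4'W + a4 + e4
    Y    = b11*A + b12*FG + b13*SBP + b14*GA + b15*CPG + G5'W + a5 + e5

with Gaussian residuals, so every downstream estimator can be tested
against ground truth that is known in closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "MissingnessModel",
    "SimulatedCohort",
    "generate_cohort",
    "inject_missingness",
    "confounder_design",
    "closed_form_deltas",
    "analysis_frame",
    "simulate_genotypes",
    "write_cohort",
    "DEFAULT_VISITS",
    "STRUCTURAL_CONFOUNDERS",
]


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


#: Scheduled follow-up months: birth, ~3 weeks, then quarterly to 18 months,
#: semi-annually/annually to 78 months.
DEFAULT_VISITS: tuple[int, ...] = (0, 1, 3, 6, 9, 12, 15, 18, 24, 36, 48, 54, 60, 66, 72, 78)

#: Confounders entering the structural equations (standardized internally).
#: Ethnicity enters as two dummies against the largest group.
STRUCTURAL_CONFOUNDERS: tuple[str, ...] = (
    "mat_age", "mat_education", "mat_income", "mat_height", "mat_ppbmi",
    "parity", "smoke_home", "pat_height", "pat_weight", "child_sex", "prs",
    "eth_malay", "eth_indian",
)

# (mean, sd) used to standardize continuous confounders inside the
# structural equations; chosen to be realistic for a Southeast-Asian
# mother-offspring cohort rather than to reproduce any particular dataset.
_CONT_MARGINALS: dict[str, tuple[float, float]] = {
    "mat_age": (31.0, 5.0),
    "mat_height": (158.0, 5.6),
    "mat_ppbmi": (22.8, 4.4),
    "pat_age": (34.5, 5.9),
    "pat_height": (171.0, 6.2),
    "pat_weight": (75.5, 14.3),
}

_DEFAULT_PATH_COEFS: dict[str, float] = {
    # treatment -> mediator / methylation / outcome
    "beta1": 0.13,    # ART -> fasting glucose (mmol/L)
    "beta2": 2.0,     # ART -> pregnancy SBP (mmHg)
    "beta4": -0.30,   # ART -> gestational age (weeks)
    "beta7": -0.50,   # ART -> fetal CpG residual (SD units)
    "beta11": -2.0,   # ART -> outcome, direct (outcome units at full multiplier)
    # mediator -> mediator
    "beta3": 2.0,     # FG -> SBP
    "beta5": -0.20,   # FG -> GA
    "beta6": -0.02,   # SBP -> GA
    "beta8": -0.05,   # FG -> CpG
    "beta9": -0.005,  # SBP -> CpG
    "beta10": 0.02,   # GA -> CpG
    # mediator -> outcome
    "beta12": 0.30,   # FG -> Y
    "beta13": -0.02,  # SBP -> Y
    "beta14": 0.40,   # GA -> Y
    "beta15": 0.50,   # CpG -> Y
}

_DEFAULT_NOISE_SDS: dict[str, float] = {
    "fg": 0.45, "sbp_preg": 8.0, "ga_weeks": 1.5, "cpg": 0.85, "y": 4.0,
    "cpg_m": 0.95, "ogtt2h": 1.2,
}

_DEFAULT_ALPHAS: dict[str, float] = {
    "fg": 4.35, "sbp_preg": 110.0, "ga_weeks": 38.5, "cpg": 0.0,
}

# Gamma vectors: confounder -> coefficient, per equation (on standardized
# confounders). Modest, plausible magnitudes.
_DEFAULT_GAMMAS: dict[str, dict[str, float]] = {
    "fg": {"mat_ppbmi": 0.12, "mat_age": 0.05, "eth_malay": 0.05, "eth_indian": 0.05},
    "sbp_preg": {"mat_ppbmi": 2.0, "mat_age": 0.8},
    "ga_weeks": {"parity": 0.15, "smoke_home": -0.2},
    "cpg": {"mat_ppbmi": -0.08, "smoke_home": -0.05},
    "y": {"mat_height": 1.2, "pat_height": 1.0, "prs": 0.6, "child_sex": 0.8,
          "mat_ppbmi": 0.3},
    "cpg_m": {"mat_ppbmi": -0.06, "mat_age": 0.04},
}

_DEFAULT_TREATMENT_MODEL: dict[str, float] = {
    # log-odds of ART conception per SD / level of each confounder;
    # older, higher-income, nulliparous mothers are more likely treated.
    "mat_age": 0.9,
    "mat_income": 0.35,
    "mat_education": 0.2,
    "parity": -0.8,
    "smoke_home": -0.4,
    "mat_ppbmi": 0.1,
}

_SUBFERTILITY_FLAGS = ("miscarriages_gt1", "pcos", "fibroids",
                       "ovarian_cysts", "thyroid", "fertility_meds")
_EXCLUSION_FLAGS = ("excl_gt14wk", "excl_chemo", "excl_psychotropic",
                    "excl_t1dm", "excl_ivf_multiple")

# base prevalence of each maternal subfertility indicator; union ~8-9%
_FLAG_BASE_RATES: dict[str, float] = {
    "miscarriages_gt1": 0.020, "pcos": 0.012, "fibroids": 0.018,
    "ovarian_cysts": 0.012, "thyroid": 0.014, "fertility_meds": 0.018,
}


@dataclass
class MissingnessModel:
    """Logistic MAR models for covariate missingness and visit dropout.

    ``covariate_models`` maps a subject column to ``(intercept, coefs)``
    where ``coefs`` maps standardized-confounder (or ``"art"``) names to
    log-odds coefficients for that cell being missing.  ``dropout``
    specifies a per-visit discrete hazard of dropping out (monotone: once
    dropped, all later visits are unobserved); birth is always observed.
    """

    covariate_models: dict[str, tuple[float, dict[str, float]]] = field(default_factory=dict)
    dropout_intercept: float = -np.inf      # logit of per-visit dropout hazard
    dropout_coefs: dict[str, float] = field(default_factory=dict)

    @classmethod
    def realistic(cls) -> "MissingnessModel":
        """Defaults emulating observed cohort missingness: heavy paternal
        missingness (~35%), moderate pre-pregnancy BMI (~9%), sparse
        sociodemographics, and ~2%/visit dropout."""
        cov = {
            "pat_age": (logit(0.33), {"mat_income": -0.15}),
            "pat_height": (logit(0.37), {"mat_income": -0.15}),
            "pat_weight": (logit(0.37), {"mat_income": -0.15}),
            "mat_ppbmi": (logit(0.09), {}),
            "mat_height": (logit(0.025), {}),
            "mat_income": (logit(0.06), {}),
            "smoke_home": (logit(0.045), {}),
        }
        return cls(covariate_models=cov,
                   dropout_intercept=logit(0.02),
                   dropout_coefs={"art": -0.15, "mat_education": -0.1})


@dataclass
class GeneratorConfig:
    """Everything that defines a simulated cohort draw.

    Defaults reproduce the study conditions the analysis is designed for:
    83 treated vs 1095 untreated singletons, a 16-visit schedule to 78
    months, confounded assignment bounded away from 0 and 1, and the
    linear structural system above with an ART effect that ramps up
    linearly with age.
    """

    n_treated: int = 83
    n_untreated: int = 1095
    seed: int = 0
    true_path_coefs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PATH_COEFS))
    gammas: dict[str, dict[str, float]] = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_GAMMAS.items()})
    alphas: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ALPHAS))
    noise_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SDS))
    treatment_model: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TREATMENT_MODEL))
    visit_schedule: tuple[int, ...] = DEFAULT_VISITS
    outcome: str = "height_cm"
    fetal_cpgs: tuple[str, ...] = ("cg03904042",)
    maternal_cpgs: tuple[str, ...] = ("cg03904042",)
    # negative-control knobs (all zero under the imprinting-null default)
    maternal_cpg_art_coef: float = 0.0
    maternal_cpg_outcome_coef: float = 0.0
    unmeasured_confounder_to_cpgm: float = 0.0
    unmeasured_confounder_to_y: float = 0.0
    missingness: MissingnessModel | None = None
    positivity_bounds: tuple[float, float] = (1e-5, 0.95)

    @property
    def n_total(self) -> int:
        return self.n_treated + self.n_untreated

    def validate(self) -> None:
        if self.n_treated < 1 or self.n_untreated < 1:
            raise ConfigError("both arms need at least one subject")
        for name, sd in self.noise_sds.items():
            if not sd > 0:
                raise ConfigError(f"noise SD for {name!r} must be positive, got {sd}")
        sched = tuple(self.visit_schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigError("visit_schedule must be strictly increasing")
        lo, hi = self.positivity_bounds
        if not (0 <= lo < hi <= 1):
            raise ConfigError("positivity_bounds must satisfy 0 <= lo < hi <= 1")


@dataclass
class SimulatedCohort:
    """A generated cohort: wide subject table, long visit table, truth."""

    subjects: pd.DataFrame
    visits: pd.DataFrame
    truth: dict


def _standardize(col: pd.Series, name: str) -> pd.Series:
    mean, sd = _CONT_MARGINALS.get(name, (0.0, 1.0))
    return (col - mean) / sd


def confounder_design(subjects: pd.DataFrame) -> pd.DataFrame:
    """Standardized confounder design used by the structural equations.

    Continuous confounders are centered/scaled by their configured
    marginals (so coefficients are per-SD); ethnicity enters as two
    dummies; flags and ordinal scores pass through.
    """
    out = pd.DataFrame(index=subjects.index)
    for name in STRUCTURAL_CONFOUNDERS:
        if name == "eth_malay":
            out[name] = (subjects["mat_ethnicity"] == "malay").astype(float)
        elif name == "eth_indian":
            out[name] = (subjects["mat_ethnicity"] == "indian").astype(float)
        elif name in _CONT_MARGINALS:
            out[name] = _standardize(subjects[name].astype(float), name)
        else:
            out[name] = subjects[name].astype(float)
    return out


def _gamma_contrib(design: pd.DataFrame, gamma: Mapping[str, float]) -> np.ndarray:
    v = np.zeros(len(design))
    for name, coef in gamma.items():
        v += coef * design[name].to_numpy()
    return v


def _draw_confounders(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_total
    d = pd.DataFrame({"subject_id": [f"S{i:05d}" for i in range(n)]})
    d["mat_age"] = rng.normal(31.0, 5.0, n).clip(18, 48)
    d["mat_ethnicity"] = rng.choice(["chinese", "malay", "indian"], size=n,
                                    p=[0.56, 0.26, 0.18])
    d["mat_education"] = rng.choice([0, 1, 2, 3, 4], size=n,
                                    p=[0.05, 0.26, 0.10, 0.25, 0.34]).astype(float)
    d["mat_income"] = rng.choice([0, 1, 2, 3, 4], size=n,
                                 p=[0.02, 0.13, 0.30, 0.25, 0.30]).astype(float)
    d["mat_height"] = rng.normal(158.0, 5.6, n)
    d["mat_ppbmi"] = rng.normal(22.8, 4.4, n).clip(14, 45)
    d["parity"] = rng.poisson(0.8, n).clip(0, 5).astype(float)
    d["smoke_home"] = (rng.random(n) < 0.32).astype(float)
    d["pat_age"] = (d["mat_age"] + rng.normal(3.4, 3.5, n)).clip(18, 65)
    d["pat_height"] = rng.normal(171.0, 6.2, n)
    d["pat_weight"] = (75.5 + 0.6 * (d["pat_height"] - 171.0) + rng.normal(0, 13.0, n)).clip(40, 160)
    d["pat_diabetes"] = (rng.random(n) < 0.025).astype(float)
    d["pat_htn"] = (rng.random(n) < 0.085).astype(float)
    d["child_sex"] = (rng.random(n) < 0.512).astype(float)
    d["prs"] = rng.normal(0.0, 1.0, n)
    return d


def _assign_treatment(cfg: GeneratorConfig, design: pd.DataFrame,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Confounded Bernoulli assignment with an intercept calibrated so the
    expected treated fraction equals n_treated / n_total."""
    lin = np.zeros(len(design))
    for name, coef in cfg.treatment_model.items():
        lin += coef * design[name].to_numpy()
    target = cfg.n_treated / cfg.n_total

    def gap(c: float) -> float:
        return float(expit(c + lin).mean() - target)

    intercept = brentq(gap, -30.0, 30.0)
    probs = expit(intercept + lin)
    lo, hi = cfg.positivity_bounds
    if probs.min() < lo or probs.max() > hi:
        raise ConfigError(
            f"assignment probabilities [{probs.min():.3g}, {probs.max():.3g}] "
            f"violate positivity bounds {cfg.positivity_bounds}")
    art = (rng.random(len(probs)) < probs).astype(float)
    return art, probs


def _draw_flags(d: pd.DataFrame, design: pd.DataFrame, rng: np.random.Generator) -> None:
    # subfertility indicators share the confounders that drive treatment,
    # so the flagged untreated subgroup resembles the treated arm
    age_z = design["mat_age"].to_numpy()
    bmi_z = design["mat_ppbmi"].to_numpy()
    for flag, rate in _FLAG_BASE_RATES.items():
        lp = logit(rate) + 0.35 * age_z + (0.3 * bmi_z if flag == "pcos" else 0.0)
        d[flag] = (rng.random(len(d)) < expit(lp)).astype(float)
    d["pat_age_gt40"] = (d["pat_age"] > 40).astype(float)
    pat_bmi = d["pat_weight"] / (d["pat_height"] / 100.0) ** 2
    d["pat_bmi_gt35"] = (pat_bmi > 35).astype(float)
    for flag in _EXCLUSION_FLAGS:
        d[flag] = 0.0


def growth_curve(month: np.ndarray | float) -> np.ndarray | float:
    """Smooth median trajectory for the default outcome (height, cm)."""
    return 50.0 + 27.0 * np.log1p(np.asarray(month, dtype=float) / 5.5)


def effect_multiplier(month: np.ndarray | float, schedule: Sequence[int]) -> np.ndarray | float:
    """Visit-indexed multiplier on the structural (ART and mediator)
    part of the outcome equation; linear in age so arm differences grow
    with age, reaching 1 at the final scheduled visit."""
    denom = float(max(schedule)) or 1.0   # birth-only schedule: no ramp
    return np.asarray(month, dtype=float) / denom


def closed_form_deltas(coefs: Mapping[str, float]) -> dict[str, float]:
    """Per-unit-treatment changes implied by the linear system (full
    multiplier): mediator deltas, the CpG-specific natural indirect
    effect, and the total effect, by path tracing."""
    b = {k: float(coefs.get(k, 0.0)) for k in _DEFAULT_PATH_COEFS}
    d_fg = b["beta1"]
    d_sbp = b["beta2"] + b["beta3"] * d_fg
    d_ga = b["beta4"] + b["beta5"] * d_fg + b["beta6"] * d_sbp
    d_cpg = b["beta7"] + b["beta8"] * d_fg + b["beta9"] * d_sbp + b["beta10"] * d_ga
    nie = b["beta15"] * d_cpg
    te = (b["beta11"] + b["beta12"] * d_fg + b["beta13"] * d_sbp
          + b["beta14"] * d_ga + nie)
    return {"d_fg": d_fg, "d_sbp": d_sbp, "d_ga": d_ga, "d_cpg": d_cpg,
            "nie": nie, "nde": te - nie, "te": te}


def generate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Simulate a full cohort draw.

    One RNG stream is consumed in a fixed stage order (confounders ->
    treatment -> mediators -> CpGs -> outcomes -> missingness) so the same
    seed reproduces the same tables byte-for-byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    b = {k: float(config.true_path_coefs.get(k, 0.0)) for k in _DEFAULT_PATH_COEFS}
    a = config.alphas
    sds = config.noise_sds

    d = _draw_confounders(config, rng)
    design = confounder_design(d)
    art, probs = _assign_treatment(config, design, rng)
    d["art"] = art
    _draw_flags(d, design, rng)

    n = len(d)
    # mediators, sequentially (downstream equations use centered parents
    # so intercepts stay on the clinical scale)
    fg = a["fg"] + b["beta1"] * art + _gamma_contrib(design, config.gammas["fg"]) \
        + rng.normal(0, sds["fg"], n)
    fg = np.clip(fg, 2.5, 12.0)
    fg_c = fg - a["fg"]
    sbp = a["sbp_preg"] + b["beta2"] * art + b["beta3"] * fg_c \
        + _gamma_contrib(design, config.gammas["sbp_preg"]) + rng.normal(0, sds["sbp_preg"], n)
    sbp_c = sbp - a["sbp_preg"]
    ga = a["ga_weeks"] + b["beta4"] * art + b["beta5"] * fg_c + b["beta6"] * sbp_c \
        + _gamma_contrib(design, config.gammas["ga_weeks"]) + rng.normal(0, sds["ga_weeks"], n)
    ga = np.clip(ga, 24.0, 43.0)
    ga_c = ga - a["ga_weeks"]
    ogtt = 6.5 + 1.2 * fg_c + 0.4 * art + rng.normal(0, sds["ogtt2h"], n)
    d["fg"] = fg
    d["ogtt2h"] = ogtt
    d["sbp_preg"] = sbp
    d["ga_weeks"] = ga
    d["preg_htn"] = (sbp > 140).astype(float)

    # fetal CpG residuals (standardized scale)
    cpg_core = (b["beta7"] * art + b["beta8"] * fg_c + b["beta9"] * sbp_c
                + b["beta10"] * ga_c + _gamma_contrib(design, config.gammas["cpg"]))
    cpg_values: dict[str, np.ndarray] = {}
    for cpg_id in config.fetal_cpgs:
        v = cpg_core + rng.normal(0, sds["cpg"], n)
        d[f"cpg_{cpg_id}"] = v
        cpg_values[cpg_id] = v

    # maternal CpG residuals (negative-control mediator); an optional
    # unmeasured common cause U of maternal CpG and outcome can be planted
    u = rng.normal(0.0, 1.0, n)
    for cpg_id in config.maternal_cpgs:
        vm = (config.maternal_cpg_art_coef * art
              + _gamma_contrib(design, config.gammas["cpg_m"])
              + config.unmeasured_confounder_to_cpgm * u
              + rng.normal(0, sds["cpg_m"], n))
        d[f"cpgm_{cpg_id}"] = vm

    # visit-level outcomes
    struct = (b["beta11"] * art + b["beta12"] * fg_c + b["beta13"] * sbp_c
              + b["beta14"] * ga_c + b["beta15"] * cpg_values[config.fetal_cpgs[0]]
              + _gamma_contrib(design, config.gammas["y"])
              + config.maternal_cpg_outcome_coef * d[f"cpgm_{config.maternal_cpgs[0]}"].to_numpy()
              + config.unmeasured_confounder_to_y * u)
    months = np.asarray(config.visit_schedule, dtype=float)
    mults = {int(m): float(effect_multiplier(m, config.visit_schedule)) for m in months}
    rows = []
    for m in config.visit_schedule:
        val = (growth_curve(m) + mults[int(m)] * struct
               + rng.normal(0, sds["y"], n))
        rows.append(pd.DataFrame({
            "subject_id": d["subject_id"], "visit_month": int(m),
            "measure": config.outcome, "value": val, "observed": True,
        }))
    visits = pd.concat(rows, ignore_index=True)

    deltas = closed_form_deltas(b)
    truth = {
        "path_coefs": b,
        "alphas": dict(a),
        "noise_sds": dict(sds),
        "visit_multipliers": mults,
        "deltas": deltas,
        "te_by_visit": {m: mult * deltas["te"] for m, mult in mults.items()},
        "assignment_prob_range": (float(probs.min()), float(probs.max())),
        "n_treated_realized": int(art.sum()),
        "seed": config.seed,
    }
    cohort = SimulatedCohort(subjects=d, visits=visits, truth=truth)

    if config.missingness is not None:
        subj, vis = inject_missingness(d, visits, config.missingness,
                                       seed=int(rng.integers(2**31 - 1)))
        cohort = SimulatedCohort(subjects=subj, visits=vis, truth=truth)
    return cohort


def inject_missingness(subjects: pd.DataFrame, visits: pd.DataFrame,
                       missing_model: MissingnessModel, seed: int,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply MAR covariate missingness and monotone visit dropout.

    Returns copies; the inputs are never mutated, so the complete tables
    remain available to the caller.  Covariate cells become NaN according
    to logistic models on the (standardized) confounders and arm; dropout
    is a per-visit discrete hazard — once a subject drops out, every later
    visit is unobserved and its value set to NaN with ``observed=False``.
    """
    for col, (c0, coefs) in missing_model.covariate_models.items():
        if not np.isfinite(list(coefs.values()) or [0.0]).all():
            raise ConfigError(f"non-finite missingness coefficient for {col!r}")
    rng = np.random.default_rng(seed)
    subj = subjects.copy()
    design = confounder_design(subjects)
    design = design.assign(art=subjects["art"].to_numpy())
    n = len(subj)

    for col, (c0, coefs) in missing_model.covariate_models.items():
        lp = np.full(n, float(c0))
        for name, coef in coefs.items():
            lp = lp + coef * design[name].to_numpy()
        miss = rng.random(n) < expit(lp)
        subj.loc[miss, col] = np.nan

    vis = visits.copy()
    months = np.sort(visits["visit_month"].unique())
    if np.isneginf(missing_model.dropout_intercept) and len(months) > 0:
        return subj, vis
    lp = np.full(n, float(missing_model.dropout_intercept))
    for name, coef in missing_model.dropout_coefs.items():
        lp = lp + coef * design[name].to_numpy()
    hazard = expit(lp)
    dropped = np.zeros(n, dtype=bool)
    sid_order = subjects["subject_id"].to_numpy()
    drop_month = np.full(n, np.inf)
    for m in months[1:]:                      # birth visit always observed
        newly = (~dropped) & (rng.random(n) < hazard)
        drop_month[newly] = m
        dropped |= newly
    drop_map = dict(zip(sid_order, drop_month))
    gone = vis["visit_month"].to_numpy() >= np.array([drop_map[s] for s in vis["subject_id"]])
    vis.loc[gone, "observed"] = False
    vis.loc[gone, "value"] = np.nan
    return subj, vis


def analysis_frame(cohort_or_subjects, visits: pd.DataFrame | None = None, *,
                   outcome: str = "height_cm", month: int = 72,
                   observed_only: bool = True) -> pd.DataFrame:
    """Merge one visit's outcome into the subject table for modelling.

    Accepts either a :class:`SimulatedCohort` or ``(subjects, visits)``.
    Adds a ``y`` column plus ``y_observed``; rows with unobserved outcome
    are dropped when ``observed_only`` (the default).
    """
    if isinstance(cohort_or_subjects, SimulatedCohort):
        subjects = cohort_or_subjects.subjects
        visits = cohort_or_subjects.visits
    else:
        subjects = cohort_or_subjects
        if visits is None:
            raise ValueError("visits table required")
    sel = visits[(visits["visit_month"] == month) & (visits["measure"] == outcome)]
    merged = subjects.merge(
        sel[["subject_id", "value", "observed"]].rename(
            columns={"value": "y", "observed": "y_observed"}),
        on="subject_id", how="left")
    if observed_only:
        merged = merged[merged["y_observed"].fillna(False).astype(bool)].reset_index(drop=True)
    return merged


def simulate_genotypes(n_subjects: int, n_snps: int, seed: int,
                       block_size: int = 5, within_block_r: float = 0.9,
                       spacing_bp: int = 100_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy genotype matrix with block-wise linkage disequilibrium.

    SNPs are laid out in blocks of ``block_size`` adjacent markers whose
    allele counts are correlated (shared latent dosage), with independent
    blocks.  Returns ``(genotypes, snp_meta)`` where genotypes is subjects
    x SNPs with counts in {0,1,2} and snp_meta carries chromosome,
    1-based position, a published effect size and p-value per SNP.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.5, n_snps)
    geno = np.zeros((n_subjects, n_snps))
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        latent = rng.normal(size=(n_subjects, 2))  # two haplotype drivers
        for j in range(start, stop):
            thresh = np.quantile(latent, freqs[j], axis=0, method="linear")
            hap = np.zeros((n_subjects, 2))
            for h in range(2):
                noise = rng.normal(size=n_subjects) * np.sqrt(1 - within_block_r)
                z = np.sqrt(within_block_r) * latent[:, h] + noise
                hap[:, h] = z < np.quantile(z, freqs[j])
            geno[:, j] = hap.sum(axis=1)
    snp_ids = [f"rs{i:06d}" for i in range(n_snps)]
    meta = pd.DataFrame({
        "snp_id": snp_ids,
        "chromosome": (np.arange(n_snps) // max(1, n_snps // 2) + 1).astype(int),
        "position": (np.arange(n_snps) * spacing_bp + 1).astype(int),
        "gwas_beta": rng.normal(0, 0.05, n_snps),
        "gwas_p": 10.0 ** rng.uniform(-12, 0, n_snps),
    })
    geno_df = pd.DataFrame(geno, columns=snp_ids)
    geno_df.insert(0, "subject_id", [f"S{i:05d}" for i in range(n_subjects)])
    return geno_df, meta


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write subjects.csv, visits.csv and a metadata sidecar (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": outdir / "subjects.csv",
        "visits": outdir / "visits.csv",
        "metadata": outdir / "metadata.json",
    }
    cohort.subjects.to_csv(paths["subjects"], index=False)
    cohort.visits.to_csv(paths["visits"], index=False)
    meta = {k: v for k, v in cohort.truth.items()}
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return paths
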