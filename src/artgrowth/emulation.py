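"""Target-trial emulation: eligibility filters and comparison-arm rules.

An observational two-arm contrast between treated (ART-conceived) and all
spontaneously conceiving subjects is confounded by everything that leads a
couple to seek fertility care.  The emulation strategy builds the control
arm the way a pragmatic trial would enrol it: spontaneously conceiving
couples whose history suggests they *could* have sought treatment.  Four
rules are supported:

``primary_subfertile``
    any maternal subfertility indicator (>1 miscarriage, PCOS, uterine
    fibroids, ovarian cysts, thyroid disorder, fertility-indicative
    medications);
``subfertile_plus_paternal``
    the primary indicators plus paternal risk factors (age > 40,
    BMI > 35, diabetes, hypertension history);
``paternal_only``
    paternal risk factors alone;
``random_none``
    a seeded random draw of subjects with none of the indications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ArmRule", "ARM_RULES", "apply_eligibility", "build_comparison_arm",
           "treated_arm", "SchemaError"]


class SchemaError(KeyError):
    """A required flag column is absent from the subject table."""


MATERNAL_SUBFERTILITY_FLAGS = ("miscarriages_gt1", "pcos", "fibroids",
                               "ovarian_cysts", "thyroid", "fertility_meds")
PATERNAL_RISK_FLAGS = ("pat_age_gt40", "pat_bmi_gt35", "pat_diabetes", "pat_htn")

ELIGIBILITY_FLAGS = ("excl_gt14wk", "excl_chemo", "excl_psychotropic",
                     "excl_t1dm", "excl_ivf_multiple")


@dataclass(frozen=True)
class ArmRule:
    """A comparison-arm definition.

    ``predicates`` are flag columns combined with OR semantics — a subject
    qualifies if any one is set.  ``random_none`` instead draws
    ``sample_size`` subjects with *no* flag set, using ``seed``.
    """

    name: str
    predicates: tuple[str, ...] = ()
    sample_size: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.name == "random_none":
            if self.sample_size is None or self.seed is None:
                raise ValueError("random_none requires sample_size and seed")
        elif not self.predicates:
            raise ValueError(f"rule {self.name!r} needs at least one predicate")


def _rules() -> dict[str, ArmRule]:
    prim = MATERNAL_SUBFERTILITY_FLAGS
    return {
        "primary_subfertile": ArmRule("primary_subfertile", prim),
        "subfertile_plus_paternal": ArmRule(
            "subfertile_plus_paternal", prim + PATERNAL_RISK_FLAGS),
        "paternal_only": ArmRule("paternal_only", PATERNAL_RISK_FLAGS),
        # default draw size mirrors a no-indication control arm of 204
        "random_none": ArmRule("random_none", (), sample_size=204, seed=0),
    }


ARM_RULES: dict[str, ArmRule] = _rules()


def apply_eligibility(records: pd.DataFrame) -> pd.DataFrame:
    """Remove subjects failing study eligibility, logging counts per criterion.

    Exclusions mirror the recruiting protocol: enrolment past 14 weeks of
    gestation, chemotherapy, psychotropic medication, pre-existing type-I
    diabetes, and treated conceptions carrying multiple gestations.
    """
    missing = [f for f in ELIGIBILITY_FLAGS if f not in records.columns]
    if missing:
        raise SchemaError(f"missing eligibility flag columns: {missing}")
    keep = pd.Series(True, index=records.index)
    for flag in ELIGIBILITY_FLAGS:
        hit = records[flag].fillna(0).astype(bool)
        if flag == "excl_ivf_multiple":
            hit = hit & records["art"].astype(bool)
        n_excl = int((keep & hit).sum())
        if n_excl:
            logger.info("eligibility: excluded %d subject(s) on %s", n_excl, flag)
        keep &= ~hit
    return records[keep].reset_index(drop=True)


def treated_arm(records: pd.DataFrame) -> pd.DataFrame:
    """The treated arm, passed through unchanged."""
    return records[records["art"].astype(bool)].reset_index(drop=True)


def build_comparison_arm(records: pd.DataFrame, rule: ArmRule | str) -> pd.DataFrame:
    """Select the untreated comparison arm under ``rule``.

    Predicates combine by OR.  For ``random_none`` a seeded uniform draw of
    ``sample_size`` subjects with every indication flag unset is returned.
    """
    if isinstance(rule, str):
        rule = ARM_RULES[rule]
    untreated = records[~records["art"].astype(bool)]
    all_flags = tuple(dict.fromkeys(
        MATERNAL_SUBFERTILITY_FLAGS + PATERNAL_RISK_FLAGS))
    needed = rule.predicates if rule.predicates else all_flags
    missing = [f for f in needed if f not in records.columns]
    if missing:
        raise SchemaError(f"missing flag columns: {missing}")

    if rule.name == "random_none":
        no_flags = ~untreated[list(all_flags)].fillna(0).astype(bool).any(axis=1)
        pool = untreated[no_flags]
        if rule.sample_size > len(pool):
            raise ValueError(
                f"random_none requested {rule.sample_size} subjects but only "
                f"{len(pool)} have no indication flags")
        drawn = pool.sample(n=rule.sample_size,
                            random_state=rule.seed).sort_index()
        return drawn.reset_index(drop=True)

    qualifies = untreated[list(rule.predicates)].fillna(0).astype(bool).any(axis=1)
    return untreated[qualifies].reset_index(drop=True)


def emulated_trial(records: pd.DataFrame, rule: ArmRule | str) -> pd.DataFrame:
    """Treated arm plus the rule's comparison arm, stacked."""
    return pd.concat([treated_arm(records), build_comparison_arm(records, rule)],
                     ignore_index=True)
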