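"""Clinical derivation formulas and measurement-protocol rules.

Shepard estimated fetal weight, HOMA indices with the low-glucose
missingness rule, the repeat-and-average blood-pressure protocol, the
length/height +0.7 cm harmonization, LMS z-scores against a pluggable
reference chart, and percent-difference reporting for log-scale models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "shepard_efw", "homa_indices", "average_bp", "length_height_harmonize",
    "percent_difference", "lms_zscore", "ReferenceChart",
    "make_synthetic_chart", "bonferroni_threshold",
]


def shepard_efw(bpd_cm: float, ac_cm: float) -> float:
    """Estimated fetal weight (kg) from biparietal diameter and abdominal
    circumference, both in centimeters:

        EFW = 10^(-1.7492 + 0.166*BPD + 0.046*AC - 2.646*AC*BPD/1000)
    """
    if bpd_cm <= 0 or ac_cm <= 0:
        raise ValueError("BPD and AC must be positive (centimeters)")
    exponent = -1.7492 + 0.166 * bpd_cm + 0.046 * ac_cm - 2.646 * ac_cm * bpd_cm / 1000.0
    return 10.0 ** exponent


def homa_indices(fasting_glucose_mmol: float, fasting_insulin_miu: float,
                 ) -> tuple[float, float]:
    """Homeostatic model assessment indices from fasting glucose (mmol/L)
    and insulin (mIU/L).

    Returns ``(homa_beta, homa_ir)``.  HOMA-beta = 20*insulin/(glucose-3.5)
    is set to NaN when glucose <= 3.5 mmol/L (the formula degenerates);
    HOMA-IR = insulin*glucose/22.5 is always computed.
    """
    if fasting_glucose_mmol <= 0:
        raise ValueError("fasting glucose must be positive")
    if fasting_insulin_miu < 0:
        raise ValueError("fasting insulin must be non-negative")
    homa_ir = fasting_insulin_miu * fasting_glucose_mmol / 22.5
    if fasting_glucose_mmol <= 3.5:
        return math.nan, homa_ir
    homa_beta = 20.0 * fasting_insulin_miu / (fasting_glucose_mmol - 3.5)
    return homa_beta, homa_ir


def average_bp(readings: Sequence[tuple[float, float]],
               ) -> tuple[float, float, bool]:
    """Summarize repeated (systolic, diastolic) readings per protocol.

    A third reading is required when either pressure differs by more than
    10 mmHg between the first two; the summary is the simple mean of all
    supplied valid readings.  Returns ``(sbp_mean, dbp_mean, needed_third)``.
    """
    if len(readings) < 2:
        raise ValueError("protocol requires at least two readings")
    (s1, d1), (s2, d2) = readings[0], readings[1]
    needed_third = abs(s1 - s2) > 10 or abs(d1 - d2) > 10
    if needed_third and len(readings) == 2:
        logger.warning("third reading indicated (delta > 10 mmHg) but only "
                       "two supplied; averaging the two")
    arr = np.asarray(readings, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean()), needed_third


def length_height_harmonize(value_cm: float, mode: str) -> float:
    """Harmonize standing height to recumbent-length scale (+0.7 cm).

    ``mode`` is ``"length"`` (pass-through) or ``"height"`` (add the
    standard 0.7 cm correction used when only standing height is available
    where length is expected).
    """
    if value_cm <= 0:
        raise ValueError("measurement must be positive")
    if mode == "length":
        return value_cm
    if mode == "height":
        return value_cm + 0.7
    raise ValueError(f"mode must be 'length' or 'height', got {mode!r}")


def percent_difference(beta_log_scale, ci: tuple[float, float] | None = None):
    """Convert a natural-log-outcome model coefficient to a percent
    difference, (exp(beta) - 1) * 100; optionally transforms both CI
    endpoints the same way."""
    pct = (np.exp(beta_log_scale) - 1.0) * 100.0
    if ci is None:
        return pct
    return pct, ((math.exp(ci[0]) - 1.0) * 100.0, (math.exp(ci[1]) - 1.0) * 100.0)


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Family-wise error threshold alpha / m."""
    if not 0 < alpha <= 1 or n_comparisons < 1:
        raise ValueError("need 0 < alpha <= 1 and n_comparisons >= 1")
    return alpha / n_comparisons


@dataclass
class ReferenceChart:
    """LMS growth-reference table: per (sex, measure), rows of age in days
    with skewness power L, median M, and coefficient of variation S.

    The shipped chart is synthetic (smooth curves); real reference tables
    in the same delimited format are accepted interchangeably.
    """

    table: pd.DataFrame  # columns: sex, age_days, measure, L, M, S

    def __post_init__(self):
        req = {"sex", "age_days", "measure", "L", "M", "S"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"chart needs columns {sorted(req)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("chart medians and coefficients of variation must be positive")
        for (sex, measure), grp in self.table.groupby(["sex", "measure"]):
            ages = grp["age_days"].to_numpy()
            if not (np.diff(ages) > 0).all():
                raise ValueError(f"ages not strictly increasing for {sex}/{measure}")

    def lms_at(self, sex: str, age_days: float, measure: str,
               ) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at exact age in days."""
        grp = self.table[(self.table["sex"] == sex) & (self.table["measure"] == measure)]
        if grp.empty:
            raise KeyError(f"chart has no rows for sex={sex!r}, measure={measure!r}")
        ages = grp["age_days"].to_numpy(dtype=float)
        if age_days < ages[0] or age_days > ages[-1]:
            raise ValueError(
                f"age {age_days} days outside chart coverage [{ages[0]}, {ages[-1]}]")
        out = []
        for col in ("L", "M", "S"):
            out.append(float(np.interp(age_days, ages, grp[col].to_numpy(dtype=float))))
        return tuple(out)  # type: ignore[return-value]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceChart":
        return cls(pd.read_csv(path))


def lms_zscore(value: float, sex: str, age_days: float, measure: str,
               chart: ReferenceChart) -> float:
    """Age- and sex-standardized z-score via the LMS transform:

        z = ((value/M)^L - 1) / (L*S)   if L != 0
        z = ln(value/M) / S             if L == 0

    with (L, M, S) interpolated at the exact age in days.
    """
    if value <= 0:
        raise ValueError("measurement must be positive")
    L, M, S = chart.lms_at(sex, age_days, measure)
    if abs(L) < 1e-12:
        return math.log(value / M) / S
    return ((value / M) ** L - 1.0) / (L * S)


def lms_inverse(z: float, sex: str, age_days: float, measure: str,
                chart: ReferenceChart) -> float:
    """Value at a given z — the algebraic inverse of :func:`lms_zscore`."""
    L, M, S = chart.lms_at(sex, age_days, measure)
    if abs(L) < 1e-12:
        return M * math.exp(z * S)
    return M * (1.0 + L * S * z) ** (1.0 / L)


def make_synthetic_chart(max_age_days: int = 2400,
                         step_days: int = 30) -> ReferenceChart:
    """A smooth synthetic LMS chart for height, weight and BMI.

    Medians follow simple parametric growth curves with a small sex
    offset; L and S vary gently with age.  Intended for testing and demo
    pipelines, not clinical use.
    """
    ages = np.arange(0, max_age_days + 1, step_days, dtype=float)
    rows = []
    for sex, off in (("M", 1.0), ("F", 0.0)):
        t = ages / 30.44  # months
        m_height = 49.5 + off + 27.0 * np.log1p(t / 5.5)
        m_weight = 3.3 + 0.15 * off + 2.2 * np.log1p(t / 2.0) + 0.12 * t
        m_bmi = 13.5 + 0.2 * off + 3.0 * np.exp(-t / 10.0) + 0.008 * t
        for measure, M, L, S in (
            ("height_cm", m_height, np.ones_like(t), np.full_like(t, 0.038)),
            ("weight_kg", m_weight, np.full_like(t, 0.2), 0.11 + 0.00025 * t),
            ("bmi", m_bmi, np.full_like(t, -1.0), np.full_like(t, 0.085)),
        ):
            for a, mm, ll, ss in zip(ages, M, L, S):
                rows.append((sex, a, measure, ll, mm, ss))
    return ReferenceChart(pd.DataFrame(
        rows, columns=["sex", "age_days", "measure", "L", "M", "S"]))


def mean_skinfold(repeats: Iterable[float]) -> float:
    """Summary of repeated skinfold calipers readings: the plain mean of
    the 4-5 supplied repeats, no trimming."""
    vals = [float(v) for v in repeats]
    if not vals:
        raise ValueError("no skinfold readings supplied")
    if any(v <= 0 for v in vals):
        raise ValueError("skinfold readings must be positive (mm)")
    return float(np.mean(vals))
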