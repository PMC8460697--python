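"""End-to-end orchestration: simulate/load -> eligibility -> arm ->
derive -> impute -> estimate -> CpG scan -> mediate, with a manifest.

Every stage writes a delimited-text artifact into the run directory and
the manifest records seeds, the configuration hash, and the artifact
list, so rerunning with the same configuration reproduces every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emulation, mediation
from .effects import (PRE_PLUS_PREGNANCY, PRE_PREGNANCY, adjusted_effect,
                      fit_weights, weighted_effect)
from .measures import bonferroni_threshold, make_synthetic_chart, lms_zscore
from .methylation import candidate_cpg_scan
from .mice import chained_impute
from .synthetic import (GeneratorConfig, MissingnessModel, analysis_frame,
                        generate_cohort, write_cohort)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_tables"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``generator`` / ``input_dir`` must be provided;
    ``input_dir`` points at subjects.csv + visits.csv written earlier.
    """

    out_dir: str
    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    arm_rule: str = "primary_subfertile"
    covset: str = "pre_pregnancy"
    seed: int = 0
    analysis_months: tuple[int, ...] = (36, 72)
    outcome: str = "height_cm"
    m_imputations: int = 5
    mice_cycles: int = 5
    n_boot: int = 100
    cpg_columns: tuple[str, ...] = ()
    run_mediation: bool = True

    def validate(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("exactly one of generator / input_dir must be set")


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir", None)    # hash covers the analysis, not its location
    return hashlib.sha256(json.dumps(payload, default=enc,
                                     sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "seed": config.seed,
                "stages": [], "artifacts": []}

    def record(stage: str, *paths: Path):
        manifest["stages"].append(stage)
        manifest["artifacts"].extend(str(p.relative_to(out)) for p in paths)

    # simulate / load
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        paths = write_cohort(cohort, out / "cohort")
        subjects, visits = cohort.subjects, cohort.visits
        record("simulate", *paths.values())
    else:
        subjects = pd.read_csv(Path(config.input_dir) / "subjects.csv")
        visits = pd.read_csv(Path(config.input_dir) / "visits.csv")
        manifest["stages"].append("load")

    # eligibility + arm
    eligible = emulation.apply_eligibility(subjects)
    trial = emulation.emulated_trial(eligible, config.arm_rule)
    p = out / "trial_subjects.csv"
    trial.to_csv(p, index=False)
    record("eligibility+arm", p)

    # derive: z-scores for the outcome at analysis visits via the
    # synthetic reference chart
    chart = make_synthetic_chart()
    chart_path = out / "reference_chart.csv"
    chart.to_csv(chart_path)
    record("derive", chart_path)

    covset = {"pre_pregnancy": PRE_PREGNANCY,
              "pre_plus_pregnancy": PRE_PLUS_PREGNANCY}[config.covset]

    rows = []
    rng = np.random.SeedSequence(config.seed)
    seeds = iter(int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in rng.spawn(64))
    for month in config.analysis_months:
        frame = analysis_frame(trial, visits, outcome=config.outcome, month=month)
        # crude
        crude = adjusted_effect(frame, dataclasses.replace(covset, variables=()),
                                outcome="y", visit_month=month)
        crude.model_tag = "crude"
        rows.append(crude)
        # impute -> adjusted
        model_cols = ["art", "y", *covset.variables]
        imp = chained_impute(frame[model_cols], m=config.m_imputations,
                             seed=next(seeds), n_cycles=config.mice_cycles,
                             variables=[c for c in covset.variables
                                        if frame[c].isna().any()])
        adj = adjusted_effect(frame, covset, imputations=imp,
                              outcome="y", visit_month=month)
        rows.append(adj)
        # IPW: standardization over the full eligible cohort (the
        # weighting alternative to arm restriction)
        full_frame = analysis_frame(eligible, visits, outcome=config.outcome,
                                    month=month, observed_only=False)
        try:
            wf = fit_weights(full_frame, covset)
            rows.append(weighted_effect(full_frame, wf, outcome="y",
                                        visit_month=month))
        except ValueError as exc:
            logger.warning("IPW skipped at month %s: %s", month, exc)
    est = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    est_path = out / "estimates.csv"
    est.to_csv(est_path, index=False)
    record("estimate", est_path)

    # CpG scan
    cpg_cols = list(config.cpg_columns) or [
        c for c in subjects.columns if c.startswith("cpg_")]
    if cpg_cols:
        assoc, skipped = candidate_cpg_scan(eligible, cpg_cols)
        scan = pd.DataFrame([dataclasses.asdict(a) for a in assoc])
        scan_path = out / "cpg_scan.csv"
        scan.to_csv(scan_path, index=False)
        record("scan", scan_path)

    # mediation
    if config.run_mediation and cpg_cols:
        med = mediation.mediation_over_visits(
            trial, visits, cpg_cols[0], config.outcome,
            config.analysis_months, n_boot=config.n_boot, seed=next(seeds))
        med_df = pd.DataFrame([{
            "visit_month": r.visit_month, "te": r.te, "nde": r.nde,
            "nie": r.nie, "te_se": r.te_se, "nde_se": r.nde_se,
            "nie_se": r.nie_se, "prop_mediated": r.prop_mediated,
            "n_boot": r.n_boot} for r in med])
        med_path = out / "mediation.csv"
        med_df.to_csv(med_path, index=False)
        record("mediate", med_path)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def render_tables(run_dir: str | Path, alpha: float = 0.05) -> pd.DataFrame:
    """Format the estimate table: one row per outcome x visit with crude
    and adjusted columns, significance markers at 0.05, 0.01 and the
    Bonferroni bound alpha / number-of-comparisons."""
    run_dir = Path(run_dir)
    est = pd.read_csv(run_dir / "estimates.csv")
    if est.empty:
        return pd.DataFrame(columns=["outcome", "visit_month", "model_tag",
                                     "formatted", "marker"])
    n_comp = len(est)
    bon = bonferroni_threshold(alpha, n_comp)

    def marker(p):
        if pd.isna(p):
            return ""
        if p < bon:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    def fmt(row):
        unit = "%" if row.get("transform") == "percent_difference" else ""
        return (f"{row['estimate']:.2f}{unit} "
                f"({row['ci_low']:.2f}, {row['ci_high']:.2f})")

    out = est.copy()
    out["formatted"] = est.apply(fmt, axis=1)
    out["marker"] = est["p_value"].map(marker)
    out.attrs["bonferroni_threshold"] = bon
    formatted_path = run_dir / "estimates_formatted.csv"
    out.to_csv(formatted_path, index=False)
    return out
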