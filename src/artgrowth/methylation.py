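"""Candidate-CpG association testing and the clump-and-threshold
polygenic risk score.

Methylation enters the analysis as batch-residualized, standardized beta
values: ``residualize_technical`` regresses each CpG on technical
indicator covariates (chip position, extraction and bisulfite-conversion
batch) and retains centered residuals.  ``candidate_cpg_scan`` fits one
adjusted linear model per a-priori CpG and flags associations at the
Bonferroni bound alpha/m and at the epigenome-wide 3.6e-8 threshold.

The polygenic score follows a two-round clump-and-threshold recipe:
greedy selection of the most significant variant per 250-kb window
pruning neighbours with squared allelic correlation > 0.5, a second pass
at 5 Mb / 0.2, a weighted allele sum using published effect sizes, and a
per-ethnicity p-value-threshold grid scored against anchor phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .measures import bonferroni_threshold

logger = logging.getLogger(__name__)

__all__ = ["CpGAssociation", "PrsResult", "residualize_technical",
           "candidate_cpg_scan", "clump", "clump_and_score",
           "EWAS_THRESHOLD"]

#: Recommended epigenome-wide significance threshold.
EWAS_THRESHOLD = 3.6e-8

#: Adjustment covariates for the per-CpG model: maternal ethnicity, age,
#: parity, pre-pregnancy BMI, and child sex.
CPG_SCAN_COVARIATES = ("mat_ethnicity", "mat_age", "parity", "mat_ppbmi", "child_sex")


@dataclass
class CpGAssociation:
    cpg_id: str
    beta: float
    se: float
    p: float
    n: int
    passes_bonferroni: bool
    passes_ewas: bool
    gene_label: str = ""


@dataclass
class PrsResult:
    scores: pd.DataFrame            # subject_id, ethnicity, raw, standardized
    chosen_thresholds: dict[str, float]
    retained_snps: dict[str, list[str]]
    grid: pd.DataFrame = field(default=None, repr=False)


def residualize_technical(beta_matrix: pd.DataFrame,
                          technical_covariates: pd.DataFrame) -> pd.DataFrame:
    """Regress each CpG column on the technical indicator design and
    return centered residuals.

    Raises on a rank-deficient technical design, naming the aliased
    indicator columns.
    """
    if len(beta_matrix) != len(technical_covariates):
        raise ValueError("covariates not aligned to samples")
    X = pd.get_dummies(technical_covariates, drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    Xm = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify aliased columns by incremental rank
        aliased, cols_kept = [], []
        for j, col in enumerate(X.columns):
            trial = Xm[:, cols_kept + [j]]
            if np.linalg.matrix_rank(trial) == len(cols_kept) + 1:
                cols_kept.append(j)
            else:
                aliased.append(col)
        raise ValueError(f"technical design is rank deficient; aliased: {aliased}")
    B = beta_matrix.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(Xm, B, rcond=None)
    resid = B - Xm @ coef
    resid = resid - resid.mean(axis=0)
    return pd.DataFrame(resid, columns=beta_matrix.columns, index=beta_matrix.index)


def candidate_cpg_scan(records: pd.DataFrame, cpg_columns: list[str],
                       covariates: tuple[str, ...] = CPG_SCAN_COVARIATES,
                       alpha: float = 0.05,
                       gene_labels: dict[str, str] | None = None,
                       ) -> tuple[list[CpGAssociation], list[str]]:
    """One adjusted OLS fit per candidate CpG; the treatment coefficient's
    two-sided p is compared to alpha/m (m = number of candidates tested)
    and to the epigenome-wide 3.6e-8 bound.

    Returns ``(associations, skipped)`` where ``skipped`` lists candidate
    columns absent from the table (not fatal).
    """
    present = [c for c in cpg_columns if c in records.columns]
    skipped = [c for c in cpg_columns if c not in records.columns]
    if skipped:
        logger.warning("CpG scan: %d candidate column(s) absent: %s",
                       len(skipped), skipped[:5])
    if not present:
        return [], skipped
    m = len(present)
    bon = bonferroni_threshold(alpha, m)
    covs = [c for c in covariates if c in records.columns]
    out = []
    for col in present:
        sub = records.dropna(subset=[col, "art", *covs])
        X = (pd.get_dummies(sub[covs], drop_first=True, dtype=float)
             if covs else pd.DataFrame(index=sub.index))
        X.insert(0, "art", sub["art"].astype(float))
        X.insert(0, "const", 1.0)
        fit = sm.OLS(sub[col].to_numpy(dtype=float), X).fit()
        beta, se, p = (float(fit.params["art"]), float(fit.bse["art"]),
                       float(fit.pvalues["art"]))
        out.append(CpGAssociation(
            cpg_id=col, beta=beta, se=se, p=p, n=len(sub),
            passes_bonferroni=p < bon, passes_ewas=p < EWAS_THRESHOLD,
            gene_label=(gene_labels or {}).get(col, "")))
    return out, skipped


def _allelic_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared correlation of allele counts (composite LD); monomorphic
    markers are treated as unlinked."""
    if np.std(g1) == 0 or np.std(g2) == 0:
        return 0.0
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def clump(genotypes: pd.DataFrame, snp_meta: pd.DataFrame,
          window_bp: int, r2_threshold: float,
          candidates: list[str] | None = None) -> list[str]:
    """One greedy clumping round.

    Ranked by ascending published p-value, each surviving SNP becomes an
    index; any not-yet-claimed SNP on the same chromosome within
    +/- ``window_bp`` of the index whose squared allelic correlation with
    it exceeds ``r2_threshold`` is removed.  Output order follows the
    internal p-value ranking, so input ordering is irrelevant.
    """
    meta = snp_meta.set_index("snp_id")
    ids = candidates if candidates is not None else list(meta.index)
    ranked = sorted(ids, key=lambda s: (meta.loc[s, "gwas_p"], s))
    kept: list[str] = []
    removed: set[str] = set()
    for idx_snp in ranked:
        if idx_snp in removed:
            continue
        kept.append(idx_snp)
        chrom = meta.loc[idx_snp, "chromosome"]
        pos = meta.loc[idx_snp, "position"]
        g_idx = genotypes[idx_snp].to_numpy(dtype=float)
        for other in ranked:
            if other == idx_snp or other in removed or other in kept:
                continue
            if meta.loc[other, "chromosome"] != chrom:
                continue
            if abs(meta.loc[other, "position"] - pos) > window_bp:
                continue
            if _allelic_r2(g_idx, genotypes[other].to_numpy(dtype=float)) > r2_threshold:
                removed.add(other)
    return kept


DEFAULT_P_GRID = (1e-10, 1e-8, 1e-6, 1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.5, 1.0)


def clump_and_score(genotypes: pd.DataFrame, snp_meta: pd.DataFrame,
                    ethnicity: pd.Series,
                    anchor_phenotypes: pd.DataFrame | None = None,
                    p_thresholds: tuple[float, ...] = DEFAULT_P_GRID,
                    ) -> PrsResult:
    """Two-round clump-and-threshold polygenic score.

    Round 1: 250-kb windows, prune at squared correlation > 0.5;
    round 2 (re-ranked by p): 5-Mb windows, prune at > 0.2.  The raw
    score is the allele-count sum weighted by the published coefficient.
    Per ethnicity stratum the p-value filtering threshold maximizing the
    mean absolute correlation between the standardized score and the
    anchor phenotypes (child birth weight and BMI) is retained, and the
    stratum's score standardized to mean 0, variance 1.
    """
    snp_cols = [c for c in genotypes.columns if c != "subject_id"]
    eth = ethnicity.reset_index(drop=True)
    round1 = clump(genotypes, snp_meta, 250_000, 0.5, candidates=snp_cols)
    round2 = clump(genotypes, snp_meta, 5_000_000, 0.2, candidates=round1)
    meta = snp_meta.set_index("snp_id")

    grid_rows = []
    raw_by_thresh: dict[float, np.ndarray] = {}
    for t in p_thresholds:
        snps = [s for s in round2 if meta.loc[s, "gwas_p"] <= t]
        if not snps:
            logger.warning("no SNPs retained at threshold %.3g; score is zero", t)
            raw_by_thresh[t] = np.zeros(len(genotypes))
            continue
        G = genotypes[snps].to_numpy(dtype=float)
        w = meta.loc[snps, "gwas_beta"].to_numpy(dtype=float)
        raw_by_thresh[t] = G @ w

    chosen: dict[str, float] = {}
    retained: dict[str, list[str]] = {}
    scores = pd.DataFrame({"subject_id": genotypes["subject_id"].to_numpy(),
                           "ethnicity": eth.to_numpy()})
    scores["raw"] = np.nan
    scores["standardized"] = np.nan
    for group in eth.unique():
        mask = (eth == group).to_numpy()
        best_t, best_score = None, -np.inf
        for t in p_thresholds:
            raw = raw_by_thresh[t][mask]
            sd = raw.std(ddof=0)
            if sd == 0:
                crit = -np.inf
            elif anchor_phenotypes is None:
                crit = 0.0 if best_t is None else -np.inf  # no anchors: first usable threshold
            else:
                std = (raw - raw.mean()) / sd
                rs = []
                for col in anchor_phenotypes.columns:
                    pheno = anchor_phenotypes[col].to_numpy(dtype=float)[mask]
                    ok = np.isfinite(pheno)
                    rs.append(abs(np.corrcoef(std[ok], pheno[ok])[0, 1])
                              if ok.sum() > 2 and pheno[ok].std() > 0 else 0.0)
                crit = float(np.mean(rs))
            row = {"ethnicity": group, "threshold": t, "criterion": crit}
            grid_rows.append(row)
            if crit > best_score:
                best_score, best_t = crit, t
        if best_t is None:
            best_t = p_thresholds[-1]
        chosen[group] = best_t
        retained[group] = [s for s in round2 if meta.loc[s, "gwas_p"] <= best_t]
        raw = raw_by_thresh[best_t][mask]
        sd = raw.std(ddof=0)
        scores.loc[mask, "raw"] = raw
        scores.loc[mask, "standardized"] = (raw - raw.mean()) / sd if sd > 0 else 0.0
    return PrsResult(scores=scores, chosen_thresholds=chosen,
                     retained_snps=retained, grid=pd.DataFrame(grid_rows))
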