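"""Multiple imputation by chained equations and Rubin's-rules pooling.

The imputation engine is deliberately small and transparent: each
incomplete variable is regressed on all other modelling variables in
round-robin cycles, with stochastic draws so the m completed datasets
differ.  Continuous variables use proper Bayesian linear-regression draws
(residual variance from a scaled inverse-chi-square, coefficients from
their sampling normal) so between-imputation variance is not understated;
binary and categorical variables draw from fitted class probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ImputationSet", "PooledEstimate", "chained_impute", "pool_rubin"]


@dataclass
class ImputationSet:
    """m completed datasets plus bookkeeping.

    Observed cells are identical across datasets; only originally missing
    cells differ between them.
    """

    datasets: list[pd.DataFrame]
    seed: int
    model_tags: dict[str, str] = field(default_factory=dict)
    trace: dict[str, list[float]] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m repeated fits of one parameter."""

    estimate: float
    within_var: float
    between_var: float
    m: int
    label: str = ""

    @property
    def total_var(self) -> float:
        return self.within_var + (1.0 + 1.0 / self.m) * self.between_var

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.estimate - z * self.se, self.estimate + z * self.se


def _var_kind(col: pd.Series) -> str:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        return "categorical"
    vals = set(col.dropna().unique().tolist())
    if vals <= {0, 1, 0.0, 1.0, True, False}:
        return "binary"
    return "continuous"


def _design(df: pd.DataFrame, exclude: str) -> np.ndarray:
    cols = [c for c in df.columns if c != exclude]
    X = pd.get_dummies(df[cols], drop_first=True, dtype=float)
    Xm = X.to_numpy(dtype=float)
    # column-standardize so the unpenalized logistic solver is well
    # conditioned; linear draws are scale-equivariant so this is harmless
    sd = Xm.std(axis=0)
    sd[sd == 0] = 1.0
    Xm = (Xm - Xm.mean(axis=0)) / sd
    return np.column_stack([np.ones(len(df)), Xm])


def _draw_continuous(X: np.ndarray, y: np.ndarray, obs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Bayesian linear-regression draw for the missing entries."""
    Xo, yo = X[obs], y[obs]
    n, p = Xo.shape
    beta_hat, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    dof = max(n - rank, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2 = sigma2_hat * dof / rng.chisquare(dof)
    XtX = Xo.T @ Xo
    cov = sigma2 * np.linalg.pinv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="svd")
    miss = ~obs
    return X[miss] @ beta + rng.normal(0.0, np.sqrt(sigma2), int(miss.sum()))


def _draw_binary(X: np.ndarray, y: np.ndarray, obs: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression
    yo = y[obs]
    if len(np.unique(yo)) < 2:
        return np.full(int((~obs).sum()), yo[0])
    clf = LogisticRegression(C=np.inf, max_iter=2000)
    clf.fit(X[obs], yo)
    p = clf.predict_proba(X[~obs])[:, 1]
    return (rng.random(len(p)) < p).astype(float)


def _draw_categorical(X: np.ndarray, y: pd.Series, obs: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression
    yo = y[obs]
    classes = np.unique(yo)
    if len(classes) < 2:
        return np.full(int((~obs).sum()), classes[0], dtype=object)
    clf = LogisticRegression(C=np.inf, max_iter=2000)
    clf.fit(X[obs], yo)
    probs = clf.predict_proba(X[~obs])
    idx = np.array([rng.choice(len(clf.classes_), p=pr / pr.sum()) for pr in probs])
    return clf.classes_[idx]


def chained_impute(records: pd.DataFrame, m: int = 10, seed: int = 0,
                   n_cycles: int = 10,
                   variables: list[str] | None = None) -> ImputationSet:
    """Impute missing cells in ``variables`` (default: all columns with
    any missing value) by chained equations, returning m completed
    datasets from independent chains.

    Initial fill is a random draw from each variable's observed values;
    then, per cycle, each incomplete variable is re-imputed from a
    regression on all other modelling variables (linear with posterior
    draws for continuous; logistic / multinomial probability draws for
    binary / categorical).  Mean traces of imputed values are recorded for
    convergence inspection.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    work_cols = variables if variables is not None else [
        c for c in records.columns if records[c].isna().any()]
    # predictors: every modelling-suitable column of the frame
    model_cols = [c for c in records.columns
                  if records[c].dtype != object or records[c].nunique(dropna=True) <= 10]
    model_cols = [c for c in model_cols if not c.startswith("subject_id")]
    incomplete = [c for c in work_cols if records[c].isna().any()]
    for c in incomplete:
        if records[c].isna().all():
            raise ValueError(f"variable {c!r} is 100% missing; nothing to learn from")
    if not any(not records[c].isna().any() for c in model_cols):
        raise ValueError("need at least one fully observed modelling variable")

    tags = {c: _var_kind(records[c]) for c in incomplete}
    ss = np.random.SeedSequence(seed)
    chains = ss.spawn(m)
    datasets: list[pd.DataFrame] = []
    trace: dict[str, list[float]] = {c: [] for c in incomplete}

    if not incomplete:
        return ImputationSet([records.copy() for _ in range(m)], seed, tags, trace)

    obs_masks = {c: records[c].notna().to_numpy() for c in incomplete}
    for chain_seq in chains:
        rng = np.random.default_rng(chain_seq)
        df = records.copy()
        # initial fill: random observed-value draws
        for c in incomplete:
            obs_vals = records.loc[obs_masks[c], c].to_numpy()
            n_miss = int((~obs_masks[c]).sum())
            df.loc[~obs_masks[c], c] = rng.choice(obs_vals, size=n_miss, replace=True)
        for _ in range(n_cycles):
            for c in incomplete:
                obs = obs_masks[c]
                X = _design(df[model_cols], exclude=c)
                kind = tags[c]
                if kind == "continuous":
                    y = records[c].to_numpy(dtype=float)
                    draws = _draw_continuous(X, np.nan_to_num(y), obs, rng)
                elif kind == "binary":
                    y = records[c].to_numpy(dtype=float)
                    draws = _draw_binary(X, np.nan_to_num(y), obs, rng)
                else:
                    draws = _draw_categorical(X, records[c], obs, rng)
                df.loc[~obs, c] = draws
                if kind != "categorical":
                    trace[c].append(float(np.mean(draws)) if len(draws) else np.nan)
        datasets.append(df)

    # observed cells must be untouched
    for c in incomplete:
        for df in datasets:
            assert (df.loc[obs_masks[c], c] == records.loc[obs_masks[c], c]).all()
    return ImputationSet(datasets, seed, tags, trace)


def pool_rubin(estimates: list[tuple[float, float]], label: str = "") -> PooledEstimate:
    """Combine m (estimate, se) pairs by Rubin's rules.

    point = mean of estimates; W = mean of se^2; B = sample variance of
    estimates; total variance T = W + (1 + 1/m) * B; Wald CI from the
    normal quantile.
    """
    if len(estimates) < 2:
        raise ValueError("Rubin pooling needs m >= 2 fits")
    est = np.asarray([e for e, _ in estimates], dtype=float)
    ses = np.asarray([s for _, s in estimates], dtype=float)
    W = float(np.mean(ses ** 2))
    B = float(np.var(est, ddof=1))
    return PooledEstimate(float(est.mean()), W, B, m=len(estimates), label=label)
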