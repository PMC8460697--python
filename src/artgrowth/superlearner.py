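"""Cross-validated stacking ensemble and collaborative TMLE.

The stacking ensemble ("SuperLearner") fits a library of regression
algorithms, computes out-of-fold predictions for each by k-fold
cross-validation, regresses the observed outcome on those predictions by
non-negative least squares, and uses the (normalized) coefficients to
weight full-data refits of every learner.

The collaborative targeted maximum likelihood estimator (C-TMLE) of the
average treatment effect then (1) scales the outcome to [0,1]; (2) forms
an initial outcome regression Q0(A, W) with the ensemble; (3) greedily
builds a propensity model by sequentially adding the covariate whose
resulting intercept-free logistic fluctuation — scaled outcome on the
clever covariate H(A,W) = A/g - (1-A)/(1-g) with offset logit(Q0) —
most reduces cross-validated squared error, stopping at the first
non-improvement; (4) updates Q with the winning fluctuation; and (5)
reports ATE = mean[Q*(1,W) - Q*(0,W)] back on the original scale, with a
Wald interval from the efficient-influence-function variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import expit, logit
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

logger = logging.getLogger(__name__)

__all__ = ["LearnerLibrary", "SuperLearner", "CtmleFit", "ctmle_ate",
           "default_library", "reduced_library"]

_G_BOUNDS = (0.01, 0.99)       # propensity bounding before forming H
_Q_BOUNDS = (0.005, 0.995)     # scaled-outcome prediction bounding for logit


def _make_learners(seed: int) -> dict[str, Callable[[], object]]:
    import xgboost as xgb

    return {
        "glm": lambda: LinearRegression(),
        "glm_interactions": lambda: make_pipeline(
            PolynomialFeatures(degree=2, interaction_only=True, include_bias=False),
            LinearRegression()),
        "bayes_glm": lambda: Ridge(alpha=1.0),
        "observed_mean": lambda: DummyRegressor(strategy="mean"),
        "neural_net_1hidden": lambda: make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(5,), max_iter=400,
                         random_state=seed, learning_rate_init=0.01)),
        "boosted_trees": lambda: xgb.XGBRegressor(
            max_depth=3, n_estimators=100, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbosity=0),
    }


@dataclass
class LearnerLibrary:
    """Named learner factories plus the cross-validation fold count."""

    names: tuple[str, ...]
    k_folds: int = 5

    def factories(self, seed: int) -> dict[str, Callable[[], object]]:
        all_ = _make_learners(seed)
        unknown = [n for n in self.names if n not in all_]
        if unknown:
            raise ValueError(f"unknown learners: {unknown}")
        if len(self.names) < 2:
            raise ValueError("library needs at least two learners")
        return {n: all_[n] for n in self.names}


def default_library(k_folds: int = 5) -> LearnerLibrary:
    """The full six-algorithm library: GLM, GLM with pairwise
    interactions, ridge-penalized GLM, observed mean, one-hidden-layer
    neural net, and boosted trees."""
    return LearnerLibrary(("glm", "glm_interactions", "bayes_glm",
                           "observed_mean", "neural_net_1hidden",
                           "boosted_trees"), k_folds)


def reduced_library(k_folds: int = 5) -> LearnerLibrary:
    """A cheap two-learner library (GLM + observed mean) for simulation
    studies that repeat the estimator hundreds of times."""
    return LearnerLibrary(("glm", "observed_mean"), k_folds)


class SuperLearner:
    """Cross-validated stacking regressor with NNLS meta-weights."""

    def __init__(self, library: LearnerLibrary | None = None, seed: int = 0):
        self.library = library or default_library()
        self.seed = seed
        self.meta_weights_: dict[str, float] = {}
        self.models_: dict[str, object] = {}
        self.cv_predictions_: pd.DataFrame | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SuperLearner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < self.library.k_folds:
            raise ValueError("need at least k_folds rows")
        if not np.isfinite(y).all():
            raise ValueError("outcome must be finite")
        factories = self.library.factories(self.seed)
        kf = KFold(n_splits=self.library.k_folds, shuffle=True,
                   random_state=self.seed)
        folds = list(kf.split(X))

        cv_preds: dict[str, np.ndarray] = {}
        for name, make in factories.items():
            preds = np.empty(len(y))
            try:
                for tr, te in folds:
                    mdl = make()
                    mdl.fit(X[tr], y[tr])
                    preds[te] = mdl.predict(X[te])
                cv_preds[name] = preds
            except Exception as exc:  # drop a failing learner, keep going
                logger.warning("learner %s failed during CV (%s); dropped", name, exc)
        if not cv_preds:
            raise RuntimeError("every learner failed")

        Z = np.column_stack([cv_preds[n] for n in cv_preds])
        w, _ = nnls(Z, y)
        if w.sum() <= 0:
            w = np.ones(len(w))  # degenerate meta-fit: fall back to equal weights
        w = w / w.sum()
        self.meta_weights_ = dict(zip(cv_preds.keys(), w))
        self.cv_predictions_ = pd.DataFrame(cv_preds)

        self.models_ = {}
        for name in cv_preds:
            mdl = factories[name]()
            try:
                mdl.fit(X, y)
                self.models_[name] = mdl
            except Exception as exc:
                logger.warning("learner %s failed on refit (%s); dropped", name, exc)
                self.meta_weights_.pop(name)
        tot = sum(self.meta_weights_.values())
        self.meta_weights_ = {k: v / tot for k, v in self.meta_weights_.items()}
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for name, w in self.meta_weights_.items():
            if w > 0:
                out += w * np.asarray(self.models_[name].predict(X), dtype=float)
        return out

    def cv_risk(self, y: np.ndarray) -> dict[str, float]:
        """Cross-validated mean squared error per learner and for the
        ensemble combination of the out-of-fold predictions."""
        y = np.asarray(y, dtype=float)
        risks = {n: float(np.mean((self.cv_predictions_[n] - y) ** 2))
                 for n in self.cv_predictions_.columns}
        Z = self.cv_predictions_.to_numpy()
        w = np.array([self.meta_weights_.get(n, 0.0) for n in self.cv_predictions_.columns])
        risks["__ensemble__"] = float(np.mean((Z @ w - y) ** 2))
        return risks


def superlearner(X, y, library: LearnerLibrary | None = None, seed: int = 0,
                 ) -> tuple[Callable[[np.ndarray], np.ndarray], dict[str, float]]:
    """Functional wrapper: returns ``(predict_fn, meta_weights)``."""
    sl = SuperLearner(library, seed).fit(X, y)
    return sl.predict, sl.meta_weights_


# --------------------------------------------------------------------------
# collaborative TMLE


def _solve_epsilon(offset: np.ndarray, H: np.ndarray, ysc: np.ndarray,
                   tol: float = 1e-12, max_iter: int = 200) -> float:
    """Maximum-likelihood epsilon of the intercept-free logistic
    fluctuation expit(offset + eps*H) for the (quasi-binomial) scaled
    outcome, by Newton iteration on the score sum H*(y - mu) = 0."""
    eps = 0.0
    for _ in range(max_iter):
        mu = expit(offset + eps * H)
        score = float(np.sum(H * (ysc - mu)))
        info = float(np.sum(H * H * mu * (1 - mu)))
        if info <= 1e-12:
            break
        step = score / info
        eps += step
        if abs(step) < tol:
            break
    return eps


def _fit_g(A: np.ndarray, W: np.ndarray | None) -> Callable:
    """Propensity fit on the current covariate subset (intercept-only when
    the subset is empty); returns a bounded predictor taking either a new
    covariate matrix or, for the intercept-only case, a row count."""
    if W is None or W.shape[1] == 0:
        p = float(np.clip(A.mean(), *_G_BOUNDS))

        def predict_const(arg):
            n = arg if isinstance(arg, (int, np.integer)) else len(arg)
            return np.full(n, p)
        return predict_const
    clf = LogisticRegression(C=np.inf, max_iter=1000)
    clf.fit(W, A)

    def predict(Wnew):
        g = clf.predict_proba(Wnew)[:, 1]
        return np.clip(g, *_G_BOUNDS)
    return predict


@dataclass
class CtmleFit:
    ate: float
    se: float
    ci: tuple[float, float]
    epsilon: float
    chosen_subset: tuple[str, ...]
    g_path: list[tuple[str, float]]          # (covariate added, CV loss)
    y_bounds: tuple[float, float]
    q0: np.ndarray = field(repr=False, default=None)
    gcomp_q0_ate: float = 0.0                # epsilon = 0 identity
    influence: np.ndarray = field(repr=False, default=None)
    meta_weights: dict[str, float] = field(default_factory=dict)


def ctmle_ate(data: pd.DataFrame, outcome: str, treatment: str,
              covariates: Sequence[str], library: LearnerLibrary | None = None,
              seed: int = 0, q_predictions: tuple[np.ndarray, np.ndarray] | None = None,
              ) -> CtmleFit:
    """Collaborative TMLE of the average treatment effect.

    ``covariates`` may include categoricals (one-hot encoded internally);
    the greedy propensity search operates on the encoded columns in their
    given order (ties broken by order).  ``q_predictions`` optionally
    injects precomputed initial outcome predictions ``(Q0 at A=1, Q0 at
    A=0)`` on the *original* outcome scale, bypassing the ensemble —
    useful for misspecification experiments.
    """
    A = data[treatment].to_numpy(dtype=float)
    if len(np.unique(A)) < 2:
        raise ValueError("both treatment arms must be present")
    y = data[outcome].to_numpy(dtype=float)
    a_bound, b_bound = float(y.min()), float(y.max())
    if b_bound <= a_bound:
        raise ValueError("outcome is constant; ATE undefined")
    span = b_bound - a_bound
    ysc = (y - a_bound) / span

    Wdf = pd.get_dummies(data[list(covariates)], drop_first=True, dtype=float)
    W = Wdf.to_numpy(dtype=float)
    # column-standardize: the propensity fits are affine-invariant and the
    # unpenalized logistic solver needs well-scaled columns
    w_sd = W.std(axis=0)
    w_sd[w_sd == 0] = 1.0
    W = (W - W.mean(axis=0)) / w_sd
    cov_names = list(Wdf.columns)
    n = len(y)

    meta_weights: dict[str, float] = {}
    if q_predictions is None:
        XA = np.column_stack([A, W])
        sl = SuperLearner(library, seed).fit(XA, ysc)
        meta_weights = sl.meta_weights_
        q1 = sl.predict(np.column_stack([np.ones(n), W]))
        q0v = sl.predict(np.column_stack([np.zeros(n), W]))
    else:
        q1 = (np.asarray(q_predictions[0], dtype=float) - a_bound) / span
        q0v = (np.asarray(q_predictions[1], dtype=float) - a_bound) / span
    q1 = np.clip(q1, *_Q_BOUNDS)
    q0v = np.clip(q0v, *_Q_BOUNDS)
    qA = np.where(A == 1, q1, q0v)
    off_A = logit(qA)

    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    folds = list(kf.split(np.arange(n)))

    def cv_loss(sub_idx: list[int]) -> float:
        loss = 0.0
        for tr, te in folds:
            Wsub = W[:, sub_idx] if sub_idx else None
            gfun = _fit_g(A[tr], None if Wsub is None else Wsub[tr])
            g_tr = gfun(len(tr) if Wsub is None else Wsub[tr])
            H_tr = A[tr] / g_tr - (1 - A[tr]) / (1 - g_tr)
            eps = _solve_epsilon(off_A[tr], H_tr, ysc[tr])
            g_te = gfun(len(te) if Wsub is None else Wsub[te])
            H_te = A[te] / g_te - (1 - A[te]) / (1 - g_te)
            mu_te = expit(off_A[te] + eps * H_te)
            loss += float(np.sum((ysc[te] - mu_te) ** 2))
        return loss / n

    chosen: list[int] = []
    path: list[tuple[str, float]] = []
    best = cv_loss(chosen)
    path.append(("<none>", best))
    remaining = list(range(len(cov_names)))
    while remaining:
        losses = [cv_loss(chosen + [j]) for j in remaining]
        k = int(np.argmin(losses))        # first minimum wins on ties
        if losses[k] >= best - 1e-12:     # stop at first non-improvement
            break
        best = losses[k]
        chosen.append(remaining.pop(k))
        path.append((cov_names[chosen[-1]], best))
    if not path[1:]:
        logger.info("C-TMLE greedy search kept the empty propensity set; "
                    "fluctuation uses the marginal treatment probability")

    Wsub = W[:, chosen] if chosen else None
    gfun = _fit_g(A, Wsub)
    g = gfun(n if Wsub is None else Wsub)
    H_A = A / g - (1 - A) / (1 - g)
    epsilon = _solve_epsilon(off_A, H_A, ysc)

    H1 = 1.0 / g
    H0 = -1.0 / (1.0 - g)
    q1s = expit(logit(q1) + epsilon * H1)
    q0s = expit(logit(q0v) + epsilon * H0)
    qAs = np.where(A == 1, q1s, q0s)
    psi_sc = float(np.mean(q1s - q0s))
    ic = H_A * (ysc - qAs) + (q1s - q0s) - psi_sc
    se = float(np.std(ic, ddof=1) / np.sqrt(n)) * span
    ate = psi_sc * span
    return CtmleFit(
        ate=ate, se=se, ci=(ate - 1.96 * se, ate + 1.96 * se),
        epsilon=epsilon, chosen_subset=tuple(cov_names[j] for j in chosen),
        g_path=path, y_bounds=(a_bound, b_bound), q0=qA,
        gcomp_q0_ate=float(np.mean(q1 - q0v)) * span,
        influence=ic * span, meta_weights=meta_weights)
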