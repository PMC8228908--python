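"""Weighted super learner for binary conditional distributions.

Cross-validated stacking: each candidate algorithm is trained on V-1 folds
under the observation weights, its held-out predictions are collected, and a
convex combination minimizing the weighted negative Bernoulli log-likelihood
over the probability simplex is found. The fitted ensemble is the same convex
combination of the base learners refit on all data.

The candidate registry mirrors the families commonly used for this task in
epidemiology: an intercept-only marginal, main-terms logistic, forward
stepwise logistic (AIC), logistic with all pairwise interactions, elastic-net
penalized logistic, a smooth additive (spline) logistic, a single regression
tree, and a random forest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from ._glm import expit, fit_weighted_logit, weighted_deviance

log = logging.getLogger(__name__)

PRED_CLAMP = (1e-6, 1.0 - 1e-6)

__all__ = [
    "LearnerSpec",
    "SuperLearnerFit",
    "fit_super_learner",
    "predict_super_learner",
    "default_library",
    "REGISTRY",
]


class EstimationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Design-matrix encoding

_MAX_LEVEL_WARNINGS = 5


class _Encoder:
    """Fixes the dummy coding of a feature table at fit time.

    Numeric columns pass through; categorical/object columns are one-hot
    encoded with the first observed level as reference. Unseen levels at
    predict time map to the reference level with a logged warning.
    """

    def fit(self, X: pd.DataFrame) -> "_Encoder":
        self.columns_ = list(X.columns)
        self.levels_: dict[str, list] = {}
        for c in X.columns:
            if X[c].dtype == object or isinstance(
                X[c].dtype, pd.CategoricalDtype
            ):
                self.levels_[c] = sorted(map(str, X[c].dropna().unique()))
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise EstimationError(f"feature columns missing: {missing}")
        parts = []
        self.names_: list[str] = []
        for c in self.columns_:
            if c in self.levels_:
                col = X[c].astype(str)
                known = set(self.levels_[c])
                unseen = set(col.unique()) - known
                if unseen:
                    log.warning(
                        "column %r: unseen levels %s mapped to reference %r",
                        c, sorted(unseen), self.levels_[c][0],
                    )
                    col = col.where(col.isin(known), self.levels_[c][0])
                for lev in self.levels_[c][1:]:
                    parts.append((col == lev).to_numpy(dtype=float))
                    self.names_.append(f"{c}={lev}")
            else:
                parts.append(X[c].to_numpy(dtype=float))
                self.names_.append(c)
        if not parts:
            return np.empty((len(X), 0))
        return np.column_stack(parts)

    def fit_transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit(X).transform(X)


def _add_intercept(Z: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(Z)), Z])


# --------------------------------------------------------------------------
# Base learners


class _BaseLearner:
    def fit(self, X: pd.DataFrame, y: np.ndarray, w: np.ndarray) -> "_BaseLearner":
        raise NotImplementedError

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


class InterceptLearner(_BaseLearner):
    """Weighted marginal mean; the 'no covariates' reference model."""

    def fit(self, X, y, w):
        self.p_ = float(np.average(y, weights=w))
        return self

    def predict(self, X):
        return np.full(len(X), self.p_)


class _GlmLearner(_BaseLearner):
    """Shared machinery for the IRLS-backed logistic families."""

    ridge = 1e-8

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        return _add_intercept(self.enc_.transform(X))

    def fit(self, X, y, w):
        self.enc_ = _Encoder().fit(X)
        D = self._design(X)
        self.beta_ = fit_weighted_logit(D, y, w, ridge=self.ridge)
        return self

    def predict(self, X):
        return expit(self._design(X) @ self.beta_)


class MainTermsLogistic(_GlmLearner):
    pass


class InteractionLogistic(_GlmLearner):
    """Main terms plus all pairwise products of encoded columns."""

    ridge = 1e-6

    def _design(self, X):
        Z = self.enc_.transform(X)
        cols = [np.ones(len(Z)), *Z.T]
        for i, j in combinations(range(Z.shape[1]), 2):
            cols.append(Z[:, i] * Z[:, j])
        return np.column_stack(cols)


class StepwiseLogistic(_BaseLearner):
    """Forward selection of encoded columns by weighted AIC."""

    def fit(self, X, y, w):
        self.enc_ = _Encoder().fit(X)
        Z = self.enc_.transform(X)
        n, p = Z.shape
        ones = np.ones((n, 1))
        chosen: list[int] = []
        beta = fit_weighted_logit(ones, y, w)
        best_aic = weighted_deviance(y, expit(ones @ beta), w) + 2.0
        while len(chosen) < p:
            cand_best = None
            for j in range(p):
                if j in chosen:
                    continue
                D = np.column_stack([ones, Z[:, chosen + [j]]])
                b = fit_weighted_logit(D, y, w)
                aic = weighted_deviance(y, expit(D @ b), w) + 2.0 * D.shape[1]
                if cand_best is None or aic < cand_best[0]:
                    cand_best = (aic, j, b)
            if cand_best is None or cand_best[0] >= best_aic - 1e-9:
                break
            best_aic, j, beta = cand_best
            chosen.append(j)
        self.chosen_ = chosen
        self.beta_ = beta
        return self

    def predict(self, X):
        Z = self.enc_.transform(X)
        D = np.column_stack([np.ones(len(Z)), Z[:, self.chosen_]])
        return expit(D @ self.beta_)


class ElasticNetLogistic(_BaseLearner):
    """Penalized logistic (elastic-net) on standardized encoded columns."""

    def __init__(self, C: float = 1.0, l1_ratio: float = 0.5):
        self.C = C
        self.l1_ratio = l1_ratio

    def fit(self, X, y, w):
        self.enc_ = _Encoder().fit(X)
        Z = self.enc_.transform(X)
        if Z.shape[1] == 0:
            raise EstimationError("elastic net needs at least one feature")
        self.scaler_ = StandardScaler().fit(Z)
        self.model_ = LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            C=self.C,
            l1_ratio=self.l1_ratio,
            max_iter=5000,
            tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_.fit(self.scaler_.transform(Z), y, sample_weight=w)
        return self

    def predict(self, X):
        Z = self.scaler_.transform(self.enc_.transform(X))
        return self.model_.predict_proba(Z)[:, 1]


class SplineAdditiveLogistic(_BaseLearner):
    """Smooth additive logistic: cubic B-spline bases on continuous columns.

    Columns with more than ``min_unique`` distinct values get a spline basis;
    the rest enter linearly. A mild ridge keeps the expanded basis stable.
    """

    def __init__(self, n_knots: int = 5, min_unique: int = 10):
        self.n_knots = n_knots
        self.min_unique = min_unique

    def _expand(self, Z: np.ndarray) -> np.ndarray:
        parts = [np.ones(len(Z))]
        for j in range(Z.shape[1]):
            if j in self.splines_:
                parts.extend(self.splines_[j].transform(Z[:, [j]]).T)
            else:
                parts.append(Z[:, j])
        return np.column_stack(parts)

    def fit(self, X, y, w):
        self.enc_ = _Encoder().fit(X)
        Z = self.enc_.transform(X)
        self.splines_: dict[int, SplineTransformer] = {}
        for j in range(Z.shape[1]):
            if len(np.unique(Z[:, j])) > self.min_unique:
                st = SplineTransformer(
                    n_knots=self.n_knots, degree=3, include_bias=False
                )
                self.splines_[j] = st.fit(Z[:, [j]])
        D = self._expand(Z)
        self.beta_ = fit_weighted_logit(D, y, w, ridge=1e-4)
        return self

    def predict(self, X):
        return expit(self._expand(self.enc_.transform(X)) @ self.beta_)


class TreeLearner(_BaseLearner):
    def __init__(self, max_depth: int = 5, min_samples_leaf: int = 20, seed: int = 0):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def fit(self, X, y, w):
        self.enc_ = _Encoder().fit(X)
        self.model_ = DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
        ).fit(self.enc_.transform(X), y, sample_weight=w)
        return self

    def predict(self, X):
        if len(self.model_.classes_) == 1:
            return np.full(len(X), float(self.model_.classes_[0]))
        return self.model_.predict_proba(self.enc_.transform(X))[:, 1]


class RandomForestLearner(_BaseLearner):
    def __init__(
        self,
        n_estimators: int = 200,
        min_samples_leaf: int = 10,
        max_features: str = "sqrt",
        seed: int = 0,
    ):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.seed = seed

    def fit(self, X, y, w):
        self.enc_ = _Encoder().fit(X)
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        ).fit(self.enc_.transform(X), y, sample_weight=w)
        return self

    def predict(self, X):
        if len(self.model_.classes_) == 1:
            return np.full(len(X), float(self.model_.classes_[0]))
        return self.model_.predict_proba(self.enc_.transform(X))[:, 1]


REGISTRY: dict[str, type[_BaseLearner]] = {
    "intercept": InterceptLearner,
    "logistic_main": MainTermsLogistic,
    "logistic_stepwise": StepwiseLogistic,
    "logistic_interactions": InteractionLogistic,
    "elastic_net": ElasticNetLogistic,
    "spline_additive": SplineAdditiveLogistic,
    "tree": TreeLearner,
    "random_forest": RandomForestLearner,
}


@dataclass(frozen=True)
class LearnerSpec:
    """A named candidate algorithm with its hyperparameters."""

    name: str
    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def build(self, seed: int = 0) -> _BaseLearner:
        if self.family not in REGISTRY:
            raise EstimationError(
                f"unknown learner family {self.family!r}; "
                f"available: {sorted(REGISTRY)}"
            )
        cls = REGISTRY[self.family]
        kwargs = dict(self.hyperparameters)
        if cls in (TreeLearner, RandomForestLearner):
            kwargs.setdefault("seed", seed)
        return cls(**kwargs)


def default_library() -> list[LearnerSpec]:
    """The full candidate set for real analyses."""
    return [
        LearnerSpec("glm", "logistic_main"),
        LearnerSpec("step", "logistic_stepwise"),
        LearnerSpec("glm_interaction", "logistic_interactions"),
        LearnerSpec("glmnet", "elastic_net"),
        LearnerSpec("gam", "spline_additive"),
        LearnerSpec("rpart", "tree"),
        LearnerSpec("random_forest", "random_forest"),
    ]


# --------------------------------------------------------------------------
# Stacking


@dataclass
class SuperLearnerFit:
    """A fitted weighted super learner.

    learner_weights sum to one over the library (failed learners pinned at
    zero); cv_risks are per-learner cross-validated weighted mean negative
    Bernoulli log-likelihoods; ensemble_cv_risk is the same loss for the
    chosen combination of held-out predictions.
    """

    library: list[LearnerSpec]
    learner_weights: np.ndarray
    cv_risks: np.ndarray
    ensemble_cv_risk: float
    fold_assignment: np.ndarray
    fitted_learners: list[_BaseLearner | None]
    feature_columns: list[str]
    loss_name: str = "weighted_neg_bernoulli_loglik"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "learner": [s.name for s in self.library],
                "family": [s.family for s in self.library],
                "cv_risk": self.cv_risks,
                "weight": self.learner_weights,
            }
        )


def _mean_nll(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, *PRED_CLAMP)
    nll = -(y * np.log(p) + (1 - y) * np.log1p(-p))
    return float(np.sum(w * nll) / np.sum(w))


def _solve_simplex_weights(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, float]:
    """Minimize the weighted NLL of a convex combination of columns of Z."""
    k = Z.shape[1]
    if k == 1:
        return np.ones(1), _mean_nll(y, Z[:, 0], w)
    wn = w / w.sum()

    def objective(alpha: np.ndarray) -> tuple[float, np.ndarray]:
        p = np.clip(Z @ alpha, *PRED_CLAMP)
        nll = -(y * np.log(p) + (1 - y) * np.log1p(-p))
        grad_p = (p - y) / (p * (1 - p))
        return float(wn @ nll), Z.T @ (wn * grad_p)

    starts = [np.full(k, 1.0 / k)]
    vertex_risks = np.array([_mean_nll(y, Z[:, j], w) for j in range(k)])
    # deterministic tie-break toward the lower-index learner
    vertex_risks = vertex_risks + 1e-12 * np.arange(k)
    best_vertex = int(np.argmin(vertex_risks))
    e = np.zeros(k)
    e[best_vertex] = 1.0
    starts.append(e)

    best: tuple[np.ndarray, float] | None = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                          "jac": lambda a: np.ones_like(a)}],
            options={"maxiter": 300, "ftol": 1e-12},
        )
        alpha = np.clip(res.x, 0.0, None)
        alpha /= alpha.sum()
        risk = _mean_nll(y, Z @ alpha, w)
        if best is None or risk < best[1]:
            best = (alpha, risk)
    # the simplex contains every vertex: never do worse than the best learner
    if vertex_risks[best_vertex] < best[1]:
        best = (e, float(_mean_nll(y, Z[:, best_vertex], w)))
    return best


def fit_super_learner(
    features: pd.DataFrame,
    target: np.ndarray,
    obs_weights: np.ndarray | None,
    library: Sequence[LearnerSpec],
    n_folds: int = 10,
    seed: int = 0,
) -> SuperLearnerFit:
    """Fit the weighted super learner.

    Folds are stratified on the binary target (stabilizing rare-outcome
    splits) and fixed by ``seed``; each learner is trained under the
    observation weights. A learner raising on any fold or on the full data is
    dropped with a warning and its ensemble weight forced to zero.
    """
    y = np.asarray(target, dtype=float)
    n = len(y)
    if len(features) != n:
        raise EstimationError("features and target lengths differ")
    w = np.ones(n) if obs_weights is None else np.asarray(obs_weights, dtype=float)
    if len(w) != n:
        raise EstimationError("obs_weights length differs from target")
    if np.any(w <= 0):
        raise EstimationError("observation weights must be positive")
    if n_folds < 2:
        raise EstimationError("n_folds must be >= 2")
    if not library:
        raise EstimationError("learner library is empty")

    K = len(library)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    splits = list(skf.split(np.zeros(n), y.astype(int)))
    for f, (_, test_idx) in enumerate(splits):
        folds[test_idx] = f

    Z = np.full((n, K), np.nan)
    failed = np.zeros(K, dtype=bool)
    for k, spec in enumerate(library):
        try:
            for f, (tr, te) in enumerate(splits):
                learner = spec.build(seed=seed + 1000 * f + k)
                learner.fit(features.iloc[tr], y[tr], w[tr])
                Z[te, k] = learner.predict(features.iloc[te])
        except Exception as exc:  # noqa: BLE001 - any learner failure drops it
            failed[k] = True
            log.warning("learner %r failed in cross-validation: %s", spec.name, exc)
    if failed.all():
        raise EstimationError("all learners failed")
    Z = np.clip(Z, *PRED_CLAMP)

    live = np.flatnonzero(~failed)
    cv_risks = np.full(K, np.inf)
    for k in live:
        cv_risks[k] = _mean_nll(y, Z[:, k], w)

    alpha_live, ens_risk = _solve_simplex_weights(Z[:, live], y, w)
    weights = np.zeros(K)
    weights[live] = alpha_live

    fitted: list[_BaseLearner | None] = [None] * K
    for k in live:
        if weights[k] == 0.0 and K > 1:
            continue  # skip refits the ensemble never uses
        try:
            fitted[k] = library[k].build(seed=seed + k).fit(features, y, w)
        except Exception as exc:  # noqa: BLE001
            log.warning("learner %r failed on full data: %s", library[k].name, exc)
            weights[k] = 0.0
    if weights.sum() == 0:
        raise EstimationError("all learners failed on the full data")
    weights = weights / weights.sum()

    return SuperLearnerFit(
        library=list(library),
        learner_weights=weights,
        cv_risks=cv_risks,
        ensemble_cv_risk=float(ens_risk),
        fold_assignment=folds,
        fitted_learners=fitted,
        feature_columns=list(features.columns),
    )


def predict_super_learner(fit: SuperLearnerFit, features: pd.DataFrame) -> np.ndarray:
    """Convex combination of base-learner predictions, clamped to (0, 1)."""
    missing = [c for c in fit.feature_columns if c not in features.columns]
    if missing:
        raise EstimationError(f"feature columns missing: {missing}")
    X = features[fit.feature_columns]
    p = np.zeros(len(X))
    for wk, learner in zip(fit.learner_weights, fit.fitted_learners):
        if wk == 0.0 or learner is None:
            continue
        p += wk * np.clip(learner.predict(X), *PRED_CLAMP)
    return p
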