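"""Feature selection and the stacked survival ensemble.

Survival labels travel as an ``(n, 2)`` array ``y = [time_days, event]``
(event 1 = recurrence, 0 = censored — deaths count as censored). Two
sklearn-style estimators carry the modelling:

* :class:`ConcordanceFeatureSelector` — drops near-constant features, ranks
  the rest by absolute univariate concordance with the outcome, and greedily
  keeps top-ranked features while pruning candidates too correlated with an
  already-kept one.
* :class:`StackedSurvivalRegressor` — a pluggable bag of regressors fit to
  ``log(time)`` on event-observed patients, combined by a non-negative
  least-squares stacker trained on out-of-fold base predictions (weights are
  >= 0 and sum to 1). Censored patients are excluded from the regression loss
  but enter the concordance evaluation through every comparable pair.

Risk is defined as ``-log(predicted_time)`` — higher risk, shorter predicted
survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import DegenerateInputError, ParameterError
from .evaluation import c_index

__all__ = [
    "ConcordanceFeatureSelector",
    "StackedSurvivalRegressor",
    "ModelConfig",
    "default_registry",
    "compact_registry",
    "select_features",
    "fit_ensemble",
    "cross_validated_predictions",
    "stratify_risk",
    "pack_outcome",
]


def pack_outcome(time, event) -> np.ndarray:
    y = np.column_stack([np.asarray(time, float), np.asarray(event, float)])
    if (y[:, 0] <= 0).any():
        raise ParameterError("survival times must be positive")
    return y


def _split_y(y):
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ParameterError("y must be an (n, 2) array of [time, event]")
    return y[:, 0], y[:, 1].astype(int)


class CappedKNNRegressor(RegressorMixin, BaseEstimator):
    """Standardized kNN regression with the neighbour count capped at the
    training-set size, so small inner stacking folds remain fittable."""

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        k = max(1, min(self.n_neighbors, len(np.asarray(y))))
        self.pipeline_ = make_pipeline(StandardScaler(), KNeighborsRegressor(k))
        self.pipeline_.fit(X, y)
        return self

    def predict(self, X):
        return self.pipeline_.predict(X)


def default_registry(random_state: Optional[int] = None) -> list[tuple[str, BaseEstimator]]:
    """The default bag: regularized linear, kNN, random forest, gradient boosting."""
    return [
        ("ridge", make_pipeline(StandardScaler(), Ridge(alpha=1.0))),
        ("knn", CappedKNNRegressor(n_neighbors=5)),
        (
            "rf",
            RandomForestRegressor(
                n_estimators=80, min_samples_leaf=3, random_state=random_state
            ),
        ),
        (
            "gbm",
            GradientBoostingRegressor(
                n_estimators=80, max_depth=2, random_state=random_state
            ),
        ),
    ]


def compact_registry(random_state: Optional[int] = None) -> list[tuple[str, BaseEstimator]]:
    """A small, fast, scale-robust bag for large sweeps and permutation studies."""
    return [
        ("ridge", make_pipeline(StandardScaler(), Ridge(alpha=1.0))),
        ("knn", CappedKNNRegressor(n_neighbors=7)),
    ]


REGISTRIES: dict[str, Callable[[Optional[int]], list]] = {
    "default": default_registry,
    "compact": compact_registry,
}


class ConcordanceFeatureSelector(TransformerMixin, BaseEstimator):
    """Univariate-concordance ranking with correlation-based redundancy pruning.

    Parameters
    ----------
    variance_floor : float
        Features with population variance below this are dropped outright.
    max_features : int
        At most this many features are kept.
    correlation_cap : float
        A candidate is pruned when its absolute Pearson correlation with any
        already-kept feature exceeds this cap.
    """

    def __init__(self, variance_floor: float = 1e-10, max_features: int = 20,
                 correlation_cap: float = 0.95):
        self.variance_floor = variance_floor
        self.max_features = max_features
        self.correlation_cap = correlation_cap

    def fit(self, X, y):
        if not 0.0 < self.correlation_cap <= 1.0:
            raise ParameterError("correlation_cap must be in (0, 1]")
        X = np.asarray(X, dtype=float)
        time, event = _split_y(y)
        if event.sum() < 2:
            raise DegenerateInputError("feature selection needs >= 2 events")
        n_features = X.shape[1]
        variances = X.var(axis=0)
        alive = variances >= self.variance_floor
        if not alive.any():
            raise DegenerateInputError("all features are (near-)constant")
        scores = np.zeros(n_features)
        for j in np.where(alive)[0]:
            c, _ = c_index(time, event, X[:, j])
            scores[j] = abs(c - 0.5)
        order = sorted(np.where(alive)[0], key=lambda j: (-scores[j], j))
        kept: list[int] = []
        for j in order:
            if len(kept) >= self.max_features:
                break
            if kept:
                sub = X[:, kept]
                with np.errstate(invalid="ignore"):
                    corr = np.corrcoef(X[:, j], sub, rowvar=False)[0, 1:]
                if np.nanmax(np.abs(corr)) > self.correlation_cap:
                    continue
            kept.append(j)
        self.n_features_in_ = n_features
        self.scores_ = scores
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[kept] = True
        self.selected_indices_ = np.array(kept, dtype=int)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError("X has a different number of features than at fit time")
        return X[:, self.selected_indices_]

    def get_support(self):
        return self.support_


class StackedSurvivalRegressor(RegressorMixin, BaseEstimator):
    """NNLS-stacked bag of regressors for log survival time.

    Base learners regress ``log(time)`` on features over event-observed
    patients. The stacker solves a non-negative least-squares problem on
    out-of-fold base predictions and normalises the weights to sum to one, so
    the ensemble prediction is a convex combination in log-time space.

    Attributes (after fit): ``learners_``, ``weights_``, ``event_count_``.
    """

    def __init__(self, base_learners=None, stack_folds: int = 3,
                 random_state: Optional[int] = None):
        self.base_learners = base_learners
        self.stack_folds = stack_folds
        self.random_state = random_state

    def _registry(self):
        if self.base_learners is None:
            return default_registry(self.random_state)
        if isinstance(self.base_learners, str):
            return REGISTRIES[self.base_learners](self.random_state)
        return [(name, clone(est)) for name, est in self.base_learners]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        time, event = _split_y(y)
        obs = event == 1
        if obs.sum() < 2:
            raise DegenerateInputError("fitting needs >= 2 event-observed patients")
        Xe = X[obs]
        z = np.log(time[obs])
        registry = self._registry()
        n_events = Xe.shape[0]
        k = int(min(self.stack_folds, n_events))
        if k >= 2:
            oof = np.zeros((n_events, len(registry)))
            kf = KFold(n_splits=k, shuffle=True, random_state=self.random_state)
            for tr, te in kf.split(Xe):
                for m, (_, est) in enumerate(registry):
                    e = clone(est)
                    e.fit(Xe[tr], z[tr])
                    oof[te, m] = e.predict(Xe[te])
            w, _ = nnls(oof, z)
        else:
            w = np.ones(len(registry))
        if w.sum() <= 0:
            w = np.ones(len(registry))
        w = w / w.sum()
        self.learners_ = [(name, clone(est).fit(Xe, z)) for name, est in registry]
        self.weights_ = w
        self.event_count_ = int(obs.sum())
        self.n_features_in_ = X.shape[1]
        return self

    def _log_prediction(self, X):
        X = np.asarray(X, dtype=float)
        preds = np.column_stack([est.predict(X) for _, est in self.learners_])
        return preds @ self.weights_

    def predict(self, X) -> np.ndarray:
        """Predicted survival time in days (positive by construction)."""
        return np.exp(self._log_prediction(X))

    def predict_risk(self, X) -> np.ndarray:
        """Risk score, ``-log(predicted_time)``: higher means worse prognosis."""
        return -self._log_prediction(X)


@dataclass(frozen=True)
class ModelConfig:
    """Bundled selector/ensemble/CV configuration."""

    n_folds: int = 5
    variance_floor: float = 1e-10
    max_features: int = 20
    correlation_cap: float = 0.95
    learners: str = "default"
    stack_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")
        if not 0.0 < self.correlation_cap <= 1.0:
            raise ParameterError("correlation_cap must be in (0, 1]")


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame(np.asarray(table, dtype=float))


def select_features(table, y, cfg: ModelConfig = ModelConfig()) -> pd.DataFrame:
    """Reduced feature table per the selector's ranking-and-pruning rule."""
    df = _as_frame(table)
    sel = ConcordanceFeatureSelector(cfg.variance_floor, cfg.max_features, cfg.correlation_cap)
    sel.fit(df.to_numpy(dtype=float), y)
    out = df.iloc[:, sel.selected_indices_].copy()
    out.attrs = dict(df.attrs)
    return out


def fit_ensemble(table, y, cfg: ModelConfig = ModelConfig()):
    """Selector + stacked ensemble fitted on the full table; returns the pair."""
    df = _as_frame(table)
    sel = ConcordanceFeatureSelector(cfg.variance_floor, cfg.max_features, cfg.correlation_cap)
    X = sel.fit(df.to_numpy(dtype=float), y).transform(df.to_numpy(dtype=float))
    model = StackedSurvivalRegressor(cfg.learners, cfg.stack_folds, cfg.seed)
    model.fit(X, y)
    return sel, model


def cross_validated_predictions(table, y, cfg: ModelConfig = ModelConfig()) -> pd.DataFrame:
    """Out-of-fold predictions for every patient.

    Folds are stratified by the event indicator; selection and fitting are
    redone inside each training fold so no information leaks from held-out
    patients. Returns a DataFrame indexed like the table with columns
    ``predicted_time``, ``risk_score`` and ``fold``.
    """
    df = _as_frame(table)
    time, event = _split_y(y)
    n = len(df)
    if n < cfg.n_folds:
        raise ParameterError(f"need at least n_folds={cfg.n_folds} patients, got {n}")
    X = df.to_numpy(dtype=float)
    pred_time = np.zeros(n)
    risk = np.zeros(n)
    fold_id = np.zeros(n, dtype=int)
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                              random_state=cfg.seed + attempt)
        folds = list(skf.split(X, event))
        if all(event[tr].sum() >= 2 for tr, _ in folds):
            if attempt:
                warnings.warn("refolded to ensure events in every training fold")
            break
    else:
        raise DegenerateInputError("could not build folds with >= 2 training events each")
    for i, (tr, te) in enumerate(folds):
        sel = ConcordanceFeatureSelector(cfg.variance_floor, cfg.max_features,
                                         cfg.correlation_cap)
        Xtr = sel.fit(X[tr], pack_outcome(time[tr], event[tr])).transform(X[tr])
        model = StackedSurvivalRegressor(cfg.learners, cfg.stack_folds, cfg.seed)
        model.fit(Xtr, pack_outcome(time[tr], event[tr]))
        Xte = sel.transform(X[te])
        pred_time[te] = model.predict(Xte)
        risk[te] = model.predict_risk(Xte)
        fold_id[te] = i
    return pd.DataFrame(
        {"predicted_time": pred_time, "risk_score": risk, "fold": fold_id}, index=df.index
    )


def repeated_cv_c_index(table, y, cfg: ModelConfig = ModelConfig(), repeats: int = 3) -> float:
    """C-index averaged over independent repeated CV fold splits.

    Arm-versus-arm comparisons (the wp and radius sweeps) hinge on C-index
    differences of a few hundredths; averaging over ``repeats`` fold splits
    shrinks the split-to-split jitter of the estimate by ``sqrt(repeats)``.
    """
    from dataclasses import replace

    from .evaluation import c_index as _c

    time, event = _split_y(y)
    cs = []
    for k in range(repeats):
        preds = cross_validated_predictions(table, y, replace(cfg, seed=cfg.seed + 1000 * k))
        cs.append(_c(time, event, preds["risk_score"].to_numpy())[0])
    return float(np.mean(cs))


def stratify_risk(risk_scores) -> np.ndarray:
    """Median split into ``low`` / ``high`` risk; ties at the median go to low."""
    r = np.asarray(risk_scores, dtype=float)
    if r.size < 2:
        raise DegenerateInputError("risk stratification needs at least 2 patients")
    if np.all(r == r[0]):
        raise DegenerateInputError("all risk scores identical; stratification is degenerate")
    med = np.median(r)
    return np.where(r > med, "high", "low")
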