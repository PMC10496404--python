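"""Learner families, hyperparameter tuning and repeated cross-validation.

Six classical algorithm families are supported — SVM (RBF kernel), k-nearest
neighbours, random forest, Gaussian naive Bayes, gradient boosting and
XGBoost — each with a small named hyperparameter grid. Tuning runs repeated
stratified k-fold cross-validation (default 5 folds × 10 repeats); for every
grid point the six metrics are averaged over all folds and the point with the
highest mean F1 wins (AUC recorded alongside; undefined metrics never win).

The min–max scaler for descriptor columns is fitted *inside* each training
fold, so validation rows never contribute to the column extrema.
"""

from __future__ import annotations

import itertools
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureMatrix, ScalerState, apply_scaler, fit_scaler
from .metrics import MetricsReport, aggregate_reports, evaluate_predictions, metric_key

ALGORITHMS = ("SVM", "kNN", "RF", "NB", "GBM", "XGB")

#: Default hyperparameter grids (config-overridable). Keys use each
#: algorithm's customary tunable names; everything else stays at library
#: defaults.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"C": [0.1, 1, 10, 100], "gamma": [1e-3, 1e-2, 0.1, "scale"]},
    "kNN": {"n_neighbors": [3, 5, 7, 9, 15], "weights": ["uniform", "distance"]},
    "RF": {"n_trees": [100, 300, 500]},
    "NB": {},
    "GBM": {"learning_rate": [0.05, 0.1, 0.2], "n_trees": [100, 300, 500]},
    "XGB": {"max_depth": [3, 5, 7, 9], "min_child_weight": [1, 3, 5]},
}


class ModelingError(RuntimeError):
    pass


@dataclass(frozen=True)
class LearnerSpec:
    """An algorithm family plus its tuning grid and seed."""

    algorithm: str
    grid: Optional[dict[str, list]] = None
    fixed_seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ModelingError(f"unknown algorithm {self.algorithm!r}")
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.algorithm]
        allowed = set(DEFAULT_GRIDS[self.algorithm])
        if set(grid) - allowed:
            raise ModelingError(
                f"{self.algorithm} grid keys {sorted(set(grid) - allowed)} not tunable"
            )
        object.__setattr__(self, "grid", {k: list(v) for k, v in grid.items()})

    def grid_points(self) -> list[dict]:
        keys = sorted(self.grid)
        if not keys:
            return [{}]
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


def make_estimator(algorithm: str, params: dict, seed: int = 0):
    """Instantiate a scikit-learn / XGBoost estimator for one grid point."""
    p = dict(params)
    n_trees = p.pop("n_trees", None)
    if algorithm == "SVM":
        return SVC(kernel="rbf", random_state=seed, **p)
    if algorithm == "kNN":
        return KNeighborsClassifier(**p)
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=n_trees if n_trees is not None else 100, random_state=seed
        )
    if algorithm == "NB":
        return GaussianNB(**p)
    if algorithm == "GBM":
        return GradientBoostingClassifier(
            n_estimators=n_trees if n_trees is not None else 100, random_state=seed, **p
        )
    if algorithm == "XGB":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            tree_method="hist",
            **p,
        )
    raise ModelingError(f"unknown algorithm {algorithm!r}")


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    """Class-1 scores in [0,1]; sigmoid of the margin where no probability exists."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    margin = estimator.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margin))


@dataclass
class CVResult:
    """Outcome of tuning one (algorithm, feature set) cell on one split."""

    algorithm: str
    feature_spec: str
    best_params: dict
    metrics: MetricsReport
    split_index: Optional[int] = None
    per_point: dict = field(default_factory=dict)  # params repr -> mean F1


def tune_and_evaluate(
    spec: LearnerSpec,
    X: FeatureMatrix,
    y: Sequence[int],
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    scaler_factory=fit_scaler,
) -> CVResult:
    """Grid search under repeated stratified CV with in-fold scaling.

    ``scaler_factory`` exists for instrumentation (leakage audits); it must
    behave like :func:`gutshield.features.fit_scaler`.
    """
    y = np.asarray(y, dtype=int)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < folds:
        raise ModelingError(
            f"minority class has {class_counts.min()} members < {folds} folds; "
            "use fewer folds or a different split seed"
        )
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    fold_indices = list(cv.split(np.zeros(len(y)), y))

    best: tuple[float, float, int] | None = None  # (F1, AUC, -order) to maximize
    best_params: dict = {}
    best_report: MetricsReport | None = None
    per_point: dict[str, float] = {}
    for order, params in enumerate(spec.grid_points()):
        reports = []
        for train_idx, valid_idx in fold_indices:
            train_ids = [X.ids[i] for i in train_idx]
            valid_ids = [X.ids[i] for i in valid_idx]
            X_tr = X.rows(train_ids)
            state = scaler_factory(X_tr)
            X_tr_s = apply_scaler(state, X_tr).values
            X_va_s = apply_scaler(state, X.rows(valid_ids)).values
            est = make_estimator(spec.algorithm, params, seed=spec.fixed_seed)
            est.fit(X_tr_s, y[train_idx])
            reports.append(evaluate_predictions(y[valid_idx], _scores(est, X_va_s)))
        agg = aggregate_reports(reports)
        per_point[repr(params)] = agg.F1
        key = (metric_key(agg.F1), metric_key(agg.AUC), -order)
        if best is None or key > best:
            best, best_params, best_report = key, params, agg
    assert best_report is not None
    return CVResult(
        algorithm=spec.algorithm,
        feature_spec=X.spec.name,
        best_params=best_params,
        metrics=best_report,
        per_point=per_point,
    )


@dataclass
class TrainedMember:
    """A fitted member model: estimator + its scaler + feature-spec identity."""

    algorithm: str
    params: dict
    feature_spec: str
    scaler: ScalerState
    estimator: object
    train_ids: list[str]
    seed: int

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        if X.spec.name != self.feature_spec:
            raise ModelingError(
                f"member trained on {self.feature_spec!r}, got {X.spec.name!r}"
            )
        scaled = X if X.scaled else apply_scaler(self.scaler, X)
        return _scores(self.estimator, scaled.values)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedMember":
        with open(path, "rb") as fh:
            member = pickle.load(fh)
        if not isinstance(member, TrainedMember):
            raise ModelingError(f"{path} does not contain a trained member")
        return member


def fit_final(
    algorithm: str,
    params: dict,
    X: FeatureMatrix,
    y: Sequence[int],
    seed: int = 0,
) -> TrainedMember:
    """Fit one member on a full training matrix with chosen hyperparameters."""
    state = fit_scaler(X)
    X_s = apply_scaler(state, X)
    est = make_estimator(algorithm, params, seed=seed)
    est.fit(X_s.values, np.asarray(y, dtype=int))
    return TrainedMember(
        algorithm=algorithm,
        params=dict(params),
        feature_spec=X.spec.name,
        scaler=state,
        estimator=est,
        train_ids=list(X.ids),
        seed=seed,
    )
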