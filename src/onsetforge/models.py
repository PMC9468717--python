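"""The ten regression algorithms behind the model comparison.

Estimator internals come from scikit-learn and xgboost; this module owns the
shared contract: restriction to a selected feature set, standardization with
training statistics, cross-validated grid search maximizing R², and
determinism from a single seed. Features are standardized for every algorithm
(required for SVM/KNN/ANN, harmless for trees) so one scaling convention
holds across the comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.linear_model import (
    ElasticNet,
    HuberRegressor,
    Lasso,
    LinearRegression,
    Ridge,
)
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, cross_val_score
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import FeatureMatrix, SelectionResult

#: Algorithm identifiers: ordinary least squares, ridge, lasso, elastic net,
#: Huber, k-nearest neighbours, support-vector, random forest, gradient
#: boosting and a ReLU multilayer perceptron trained with L-BFGS.
ALGORITHMS: tuple[str, ...] = (
    "LR", "RR", "Lasso", "EN", "HR", "KNN", "SVM", "RF", "XGBoost", "ANN",
)

#: Default hyperparameter grids for the cross-validated search. Penalty
#: strengths, neighbourhood sizes, tree counts/depths and hidden-layer sizes
#: span the ranges a practitioner would scan on a cohort of ~1,000 subjects.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {},
    "RR": {"alpha": [0.01, 0.1, 1.0, 10.0]},
    "Lasso": {"alpha": [0.01, 0.1, 1.0, 10.0]},
    "EN": {"alpha": [0.01, 0.1, 1.0, 10.0], "l1_ratio": [0.2, 0.5, 0.8]},
    "HR": {"epsilon": [1.35, 2.0, 5.0]},
    "KNN": {"n_neighbors": [3, 5, 7, 11]},
    "SVM": {"C": [0.1, 1.0, 10.0], "epsilon": [0.05, 0.1, 0.5]},
    "RF": {"n_estimators": [200, 500], "max_depth": [None, 10]},
    "XGBoost": {
        "n_estimators": [200, 500],
        "max_depth": [3, 5],
        "learning_rate": [0.05, 0.1],
    },
    "ANN": {
        "hidden_layer_sizes": [(50,), (100,), (50, 25)],
        "alpha": [1e-4, 1e-3],
    },
}


def build_estimator(algorithm: str, seed: int = 0):
    """Deterministically configured base estimator for one algorithm id."""
    if algorithm == "LR":
        return LinearRegression()
    if algorithm == "RR":
        return Ridge()
    if algorithm == "Lasso":
        return Lasso(max_iter=100000, tol=1e-8)
    if algorithm == "EN":
        return ElasticNet(max_iter=100000, tol=1e-8)
    if algorithm == "HR":
        return HuberRegressor(max_iter=10000, tol=1e-8)
    if algorithm == "KNN":
        return KNeighborsRegressor()
    if algorithm == "SVM":
        return SVR()
    if algorithm == "RF":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if algorithm == "XGBoost":
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0,
                            tree_method="hist")
    if algorithm == "ANN":
        return MLPRegressor(solver="lbfgs", activation="relu",
                            random_state=seed, max_iter=5000)
    raise ValueError(f"unknown algorithm {algorithm!r}; valid: {ALGORITHMS}")


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str
    grid: dict[str, list] | None = None  # None -> DEFAULT_GRIDS[algorithm]
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid: {ALGORITHMS}"
            )

    @property
    def effective_grid(self) -> dict[str, list]:
        return DEFAULT_GRIDS[self.algorithm] if self.grid is None else self.grid


@dataclass
class FittedModel:
    """A trained predictor plus everything needed to reapply it."""

    config: ModelConfig
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    estimator: object
    best_params: dict
    cv_score: float
    grid_scores: list[float] = field(default_factory=list)


def fit(config: ModelConfig, train: FeatureMatrix,
        feature_set: SelectionResult) -> FittedModel:
    """Restrict, standardize, grid-search by CV R² and refit on all rows."""
    if not feature_set.selected:
        raise ValueError("feature set is empty")
    sub = train.restrict(feature_set.selected)

    mean = sub.values.mean(axis=0)
    sd = sub.values.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = [sub.feature_names[j] for j in zero]
        raise ValueError(f"zero-variance features after restriction: {bad}")
    X = (sub.values - mean) / sd
    y = sub.target

    cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    grid = config.effective_grid
    if grid:
        search = GridSearchCV(
            build_estimator(config.algorithm, config.seed),
            param_grid=grid, scoring="r2", cv=cv, n_jobs=1,
            error_score="raise", refit=True,
        )
        search.fit(X, y)
        estimator = search.best_estimator_
        best_params = dict(search.best_params_)
        cv_score = float(search.best_score_)
        grid_scores = [float(s) for s in search.cv_results_["mean_test_score"]]
    else:
        estimator = build_estimator(config.algorithm, config.seed)
        cv_score = float(np.mean(
            cross_val_score(estimator, X, y, scoring="r2", cv=cv, n_jobs=1)
        ))
        estimator.fit(X, y)
        best_params = {}
        grid_scores = [cv_score]

    return FittedModel(
        config=config,
        feature_names=list(sub.feature_names),
        scaler_mean=mean,
        scaler_sd=sd,
        estimator=estimator,
        best_params=best_params,
        cv_score=cv_score,
        grid_scores=grid_scores,
    )


def predict(model: FittedModel, data: FeatureMatrix) -> np.ndarray:
    """Predicted AAO (years) for every row of ``data``."""
    missing = [f for f in model.feature_names if f not in data.feature_names]
    if missing:
        raise KeyError(f"data is missing model features {missing}")
    sub = data.restrict(model.feature_names)
    X = (sub.values - model.scaler_mean) / model.scaler_sd
    return np.asarray(model.estimator.predict(X), dtype=float)


def predict_raw(model: FittedModel, values: np.ndarray) -> np.ndarray:
    """Predict from a raw (unscaled) value array ordered as feature_names."""
    X = (np.atleast_2d(values) - model.scaler_mean) / model.scaler_sd
    return np.asarray(model.estimator.predict(X), dtype=float)


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist the fitted state with a JSON sidecar of its metadata."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "format_version": 1,
        "algorithm": model.config.algorithm,
        "best_params": model.best_params,
        "feature_names": model.feature_names,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_sd": model.scaler_sd.tolist(),
        "cv_score": model.cv_score,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_model(path: str | Path) -> FittedModel:
    return joblib.load(path)
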