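"""Wrapper feature selection: StepSVM forward selection and SVM-RFE.

Both selectors score candidate subsets by the mean cross-validated R² of a
fixed support-vector regressor. The fold assignment is drawn once per
selection run and reused for every candidate evaluation, so score differences
reflect the features rather than fold noise. Tie-breaking everywhere follows
canonical feature order (earliest wins).

StepSVM starts from the best single feature and greedily adds the feature
with the largest CV-R² gain, stopping when the best gain falls below the
minimum-improvement threshold or the feature cap is reached. RFE repeatedly
drops the surviving feature with the smallest absolute linear-SVR
coefficient, then returns the nested subset with the best CV R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR, LinearSVR

from .features import FeatureMatrix, SelectionResult, StepRecord


@dataclass(frozen=True)
class SVRParams:
    """Fixed settings of the support-vector regressor used for scoring."""

    kernel: str = "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"
    tol: float = 1e-3

    def build(self) -> SVR:
        return SVR(kernel=self.kernel, C=self.C, epsilon=self.epsilon,
                   gamma=self.gamma, tol=self.tol, cache_size=200)


@dataclass(frozen=True)
class StepSVMConfig:
    min_improvement: float = 0.001
    max_features: int = 30
    n_folds: int = 10
    base_learner: SVRParams = field(default_factory=SVRParams)
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class RFEConfig:
    n_folds: int = 10
    ranking_learner_C: float = 1.0
    elimination_step: int = 1
    base_learner: SVRParams = field(default_factory=SVRParams)
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.elimination_step < 1:
            raise ValueError("elimination_step must be >= 1")


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mean) / sd


def _fold_indices(n: int, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _cv_r2(X: np.ndarray, y: np.ndarray,
           folds: list[tuple[np.ndarray, np.ndarray]],
           params: SVRParams) -> float:
    scores = []
    for train_idx, val_idx in folds:
        model = params.build().fit(X[train_idx], y[train_idx])
        pred = model.predict(X[val_idx])
        resid = y[val_idx] - pred
        tot = y[val_idx] - y[val_idx].mean()
        scores.append(1.0 - (resid @ resid) / (tot @ tot))
    return float(np.mean(scores))


def stepsvm_select(matrix: FeatureMatrix, config: StepSVMConfig) -> SelectionResult:
    """Greedy forward selection scored by fixed-fold CV R² of an SVR.

    The trace records every stage's winning candidate, its CV R² and the
    improvement over the previous score; the final stage that failed the
    improvement bar (if any) appears with ``accepted=False``.
    """
    if matrix.n_features < 2:
        raise ValueError("need at least 2 candidate features")
    if config.max_features > matrix.n_features:
        raise ValueError("max_features exceeds candidate count")

    X = _standardize(matrix.values)
    y = matrix.target
    names = matrix.feature_names
    folds = _fold_indices(matrix.n_subjects, config.n_folds, config.fold_seed)

    def best_candidate(selected_idx: list[int], remaining: list[int]):
        best_j, best_score = None, -np.inf
        for j in remaining:  # canonical order; strict > keeps earliest on ties
            score = _cv_r2(X[:, selected_idx + [j]], y, folds, config.base_learner)
            if score > best_score:
                best_j, best_score = j, score
        return best_j, best_score

    remaining = list(range(matrix.n_features))
    best_j, best_score = best_candidate([], remaining)
    selected = [best_j]
    remaining.remove(best_j)
    trace = [StepRecord(step=0, feature=names[best_j],
                        n_candidates=matrix.n_features,
                        cv_r2=best_score, improvement=None, accepted=True)]
    current = best_score

    step = 1
    while len(selected) < config.max_features and remaining:
        cand_j, cand_score = best_candidate(selected, remaining)
        improvement = cand_score - current
        accepted = improvement >= config.min_improvement
        trace.append(StepRecord(step=step, feature=names[cand_j],
                                n_candidates=len(remaining),
                                cv_r2=cand_score, improvement=improvement,
                                accepted=accepted))
        if not accepted:
            break
        selected.append(cand_j)
        remaining.remove(cand_j)
        current = cand_score
        step += 1

    return SelectionResult(
        method="crossing_correlation_stepsvm",
        selected=[names[j] for j in selected],
        trace=trace,
    )


def rfe_ranking(matrix: FeatureMatrix, config: RFEConfig) -> list[str]:
    """Elimination order (first dropped first) from refitting a linear SVR.

    At each round the surviving feature with the smallest |coefficient| is
    dropped; on ties the later feature in canonical order is dropped, so the
    earlier one survives.
    """
    X = _standardize(matrix.values)
    y = matrix.target
    names = matrix.feature_names
    surviving = list(range(matrix.n_features))
    dropped: list[int] = []
    while len(surviving) > 1:
        model = LinearSVR(C=config.ranking_learner_C, epsilon=0.0,
                          max_iter=100000, tol=1e-6,
                          random_state=config.fold_seed)
        model.fit(X[:, surviving], y)
        coefs = np.abs(model.coef_)
        n_drop = min(config.elimination_step, len(surviving) - 1)
        # sort by (|coef| asc, canonical position desc) -> later feature drops first
        order = sorted(range(len(surviving)),
                       key=lambda i: (coefs[i], -surviving[i]))
        for i in sorted(order[:n_drop], key=lambda i: surviving[i], reverse=True):
            dropped.append(surviving[i])
        surviving = [j for j in surviving if j not in dropped]
    dropped.extend(surviving)
    return [names[j] for j in dropped]


def rfe_select(matrix: FeatureMatrix, config: RFEConfig) -> SelectionResult:
    """SVM-RFE: eliminate by |coefficient|, pick the best nested subset by CV R².

    The trace records one entry per evaluated nested subset size (the feature
    field holds the feature dropped when shrinking from that size). Ties in
    CV R² go to the smaller subset.
    """
    if matrix.n_features < 2:
        raise ValueError("need at least 2 candidate features")

    names = matrix.feature_names
    elimination = rfe_ranking(matrix, config)
    # nested subsets by survival: subset of size s = last s features eliminated
    keep_order = elimination[::-1]  # most important first

    X = _standardize(matrix.values)
    y = matrix.target
    folds = _fold_indices(matrix.n_subjects, config.n_folds, config.fold_seed)
    col = {name: j for j, name in enumerate(names)}

    trace: list[StepRecord] = []
    best_size, best_score = None, -np.inf
    for size in range(1, matrix.n_features + 1):
        subset = keep_order[:size]
        idx = sorted(col[name] for name in subset)  # canonical order
        score = _cv_r2(X[:, idx], y, folds, config.base_learner)
        dropped_here = keep_order[size] if size < matrix.n_features else None
        trace.append(StepRecord(step=size, feature=dropped_here,
                                n_candidates=size, cv_r2=score,
                                improvement=None, accepted=True))
        if score > best_score:  # strict: ties keep the smaller size
            best_size, best_score = size, score

    chosen = keep_order[:best_size]
    selected = sorted(chosen, key=lambda name: col[name])
    return SelectionResult(
        method="crossing_correlation_rfe", selected=selected, trace=trace
    )
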