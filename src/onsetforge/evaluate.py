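"""Cohort splitting, the six evaluation metrics and the model comparison.

The test set is additionally partitioned at an expanded-ATXN3 threshold
(default 68 repeats) into a short-expansion and a long-expansion subset, so
every fitted model is scored on the full test set and on both subsets —
mirroring the piecewise evaluation used to compare against piecewise onset
models. One model is fitted per (feature-optimization method, algorithm)
pair; no piecewise models are fitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models as model_zoo
from .cohort import Cohort
from .features import (
    METHODS,
    FeatureMatrix,
    SelectionResult,
    correlate,
    cross_features,
    derive_features,
    select_by_correlation,
)
from .models import ALGORITHMS, FittedModel, ModelConfig
from .selection import RFEConfig, StepSVMConfig, rfe_select, stepsvm_select

logger = logging.getLogger(__name__)

SUBSETS: tuple[str, ...] = ("full_test", "cagexp_le_threshold", "cagexp_gt_threshold")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    piecewise_threshold: int = 68

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class MetricsRecord:
    """R², MAE, RMSE, MedianAE and the <5 / >10 year error-band proportions."""

    r2: float
    mae: float
    rmse: float
    median_ae: float
    proportion_lt5: float
    proportion_gt10: float
    n: int

    def __post_init__(self) -> None:
        if self.mae > self.rmse + 1e-9:
            raise ValueError("mae exceeds rmse")
        for p in (self.proportion_lt5, self.proportion_gt10):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must be in [0, 1]")
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("r2 exceeds 1")


@dataclass
class EvaluationReport:
    """Metrics per (algorithm, method, subset) plus the best full-test pair."""

    rows: dict[tuple[str, str, str], MetricsRecord | None]
    best: tuple[str, str] | None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for (algorithm, method, subset), m in self.rows.items():
            rec = {"method": method, "model": algorithm, "subset": subset}
            if m is not None:
                rec.update(
                    r2=m.r2, mae=m.mae, rmse=m.rmse, median_ae=m.median_ae,
                    prop_lt5=m.proportion_lt5, prop_gt10=m.proportion_gt10, n=m.n,
                )
            recs.append(rec)
        return pd.DataFrame(recs)


def split_cohort(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Disjoint train/test split by non-repetitive random sampling.

    Train size is floor(train_fraction * n) — 997 subjects at 0.8 give the
    797/200 split. Subject order within each part follows the input cohort.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    n_train = math.floor(spec.train_fraction * n)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    prov = dict(cohort.provenance)
    train = Cohort([cohort.subjects[i] for i in train_idx], dict(prov))
    test = Cohort([cohort.subjects[i] for i in test_idx], dict(prov))
    logger.info("split: %d train / %d test", len(train), len(test))
    return train, test


def piecewise_subsets(test: Cohort, threshold: int = 68) -> tuple[Cohort, Cohort]:
    """Partition by expanded ATXN3 allele: a2 <= threshold vs a2 > threshold."""
    le = [s for s in test.subjects if s.alleles["ATXN3"][1] <= threshold]
    gt = [s for s in test.subjects if s.alleles["ATXN3"][1] > threshold]
    prov = dict(test.provenance)
    return Cohort(le, dict(prov)), Cohort(gt, dict(prov))


def compute_metrics(actual: np.ndarray, predicted: np.ndarray) -> MetricsRecord:
    """The six evaluation metrics for one prediction vector.

    Error bands use strict inequalities: |e| < 5 and |e| > 10, so boundary
    errors fall in the middle band.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("length mismatch between actual and predicted")
    n = actual.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual values are constant; r2 undefined")
    err = actual - predicted
    abs_err = np.abs(err)
    return MetricsRecord(
        r2=1.0 - float(np.sum(err**2)) / ss_tot,
        mae=float(abs_err.mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        median_ae=float(np.median(abs_err)),
        proportion_lt5=float(np.mean(abs_err < 5.0)),
        proportion_gt10=float(np.mean(abs_err > 10.0)),
        n=int(n),
    )


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the two correlation screens.

    ``p_set1`` gates the correlation-only feature set; ``p_set2`` and
    ``r_set2`` gate the post-crossing screen feeding sets 2-4.
    """

    p_set1: float = 0.1
    p_set2: float = 0.01
    r_set2: float = 0.2


def build_feature_set(
    train_original: FeatureMatrix,
    train_crossed: FeatureMatrix,
    method: str,
    screen: ScreenConfig = ScreenConfig(),
    stepsvm_config: StepSVMConfig | None = None,
    rfe_config: RFEConfig | None = None,
) -> SelectionResult:
    """Run one feature-optimization method on training matrices."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {METHODS}")
    if method == "correlation":
        table = correlate(train_original)
        return select_by_correlation(table, p_max=screen.p_set1, method=method)
    table = correlate(train_crossed)
    gate = select_by_correlation(
        table, p_max=screen.p_set2, r_min_abs=screen.r_set2,
        method="crossing_correlation",
    )
    if method == "crossing_correlation":
        return gate
    gated = train_crossed.restrict(gate.selected)
    if method == "crossing_correlation_stepsvm":
        cfg = stepsvm_config or StepSVMConfig()
        cfg = cfg if cfg.max_features <= gated.n_features else StepSVMConfig(
            min_improvement=cfg.min_improvement,
            max_features=gated.n_features,
            n_folds=cfg.n_folds, base_learner=cfg.base_learner,
            fold_seed=cfg.fold_seed,
        )
        return stepsvm_select(gated, cfg)
    return rfe_select(gated, rfe_config or RFEConfig())


@dataclass
class ComparisonResult:
    report: EvaluationReport
    selections: dict[str, SelectionResult]
    fitted: dict[tuple[str, str], FittedModel]  # (algorithm, method)


def run_comparison(
    train: Cohort,
    test: Cohort,
    methods: list[str],
    algorithms: list[str],
    *,
    screen: ScreenConfig = ScreenConfig(),
    stepsvm_config: StepSVMConfig | None = None,
    rfe_config: RFEConfig | None = None,
    model_configs: dict[str, ModelConfig] | None = None,
    piecewise_threshold: int = 68,
    seed: int = 0,
) -> ComparisonResult:
    """Fit every (method, algorithm) pair and score it piecewise.

    Metrics are recorded for the full test set and both ATXN3-threshold
    subsets; subsets too small for metrics (fewer than 2 subjects or constant
    AAO) get ``None`` with a logged warning. The best pair is chosen by
    full-test R².
    """
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; valid: {METHODS}")
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(f"unknown algorithms {unknown}; valid: {ALGORITHMS}")

    train_orig = derive_features(train)
    test_orig = derive_features(test)
    needs_cross = any(m != "correlation" for m in methods)
    train_cross = cross_features(train_orig) if needs_cross else train_orig
    test_cross = cross_features(test_orig) if needs_cross else test_orig

    le_mask = test.atxn3_cagexp <= piecewise_threshold

    selections: dict[str, SelectionResult] = {}
    fitted: dict[tuple[str, str], FittedModel] = {}
    rows: dict[tuple[str, str, str], MetricsRecord | None] = {}

    for method in methods:
        selections[method] = build_feature_set(
            train_orig, train_cross, method, screen=screen,
            stepsvm_config=stepsvm_config, rfe_config=rfe_config,
        )
        logger.info("method %s selected %d features", method,
                    len(selections[method].selected))
        train_m = train_orig if method == "correlation" else train_cross
        test_m = test_orig if method == "correlation" else test_cross
        for algorithm in algorithms:
            config = (model_configs or {}).get(algorithm) or ModelConfig(
                algorithm=algorithm, seed=seed
            )
            model = model_zoo.fit(config, train_m, selections[method])
            fitted[(algorithm, method)] = model
            pred = model_zoo.predict(model, test_m)
            for subset_name, mask in (
                ("full_test", np.ones(len(test), dtype=bool)),
                ("cagexp_le_threshold", le_mask),
                ("cagexp_gt_threshold", ~le_mask),
            ):
                actual = test_m.target[mask]
                try:
                    rows[(algorithm, method, subset_name)] = compute_metrics(
                        actual, pred[mask]
                    )
                except ValueError as exc:
                    logger.warning("metrics undefined for %s/%s/%s: %s",
                                   algorithm, method, subset_name, exc)
                    rows[(algorithm, method, subset_name)] = None

    best = None
    best_r2 = -np.inf
    for (algorithm, method, subset_name), rec in rows.items():
        if subset_name == "full_test" and rec is not None and rec.r2 > best_r2:
            best, best_r2 = (algorithm, method), rec.r2
    report = EvaluationReport(rows=rows, best=best)
    return ComparisonResult(report=report, selections=selections, fitted=fitted)
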