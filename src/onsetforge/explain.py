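"""Shapley-value attribution for fitted AAO models.

Per-sample, per-feature contributions in years of predicted onset are
estimated by permutation sampling: for each random feature ordering, features
are switched one by one from background values to the explained sample's
values, and the prediction changes are averaged over a background sample
drawn from the training data. The base value is the mean prediction over the
background, so contributions satisfy (to sampling tolerance)

    prediction(sample) = base_value + sum(contributions).

An exact enumeration oracle over all 2^k feature subsets is provided for
small models; it is the reference the sampler is validated against. On top of
the raw attributions the module derives the global importance ranking (mean
|contribution|), dependence curves against raw feature values with an
exhaustive piecewise-linear changepoint fit, subgroup re-rankings and
per-sample additive decompositions suitable for waterfall rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .features import FeatureMatrix
from .models import FittedModel, predict_raw


@dataclass
class AttributionResult:
    base_value: float
    contributions: np.ndarray  # (n_samples, n_features), years
    feature_names: list[str]
    background_size: int
    estimator: str  # "exact" | "sampling"
    n_permutations: int
    seed: int
    sample_values: np.ndarray  # raw feature values of the explained samples
    predictions: np.ndarray  # model predictions for the explained samples

    def __post_init__(self) -> None:
        if self.estimator not in ("exact", "sampling"):
            raise ValueError(f"bad estimator {self.estimator!r}")


@dataclass(frozen=True)
class ChangepointFit:
    """Two-segment least-squares fit of a dependence curve."""

    breakpoint: float
    left_slope: float
    right_slope: float
    left_intercept: float
    right_intercept: float
    sse: float
    sse_linear: float


def _check_alignment(model: FittedModel, matrix: FeatureMatrix) -> FeatureMatrix:
    missing = [f for f in model.feature_names if f not in matrix.feature_names]
    if missing:
        raise ValueError(f"matrix missing model features {missing}")
    return matrix.restrict(model.feature_names)


def attribute(
    model: FittedModel,
    samples: FeatureMatrix,
    background: FeatureMatrix,
    n_permutations: int = 64,
    seed: int = 0,
    _chunk_rows: int = 200_000,
) -> AttributionResult:
    """Permutation-sampling Shapley attributions for every row of ``samples``.

    Each of ``n_permutations`` random orderings contributes one marginal per
    feature, averaged over the full background; deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if background.n_subjects == 0:
        raise ValueError("background is empty")
    samples_m = _check_alignment(model, samples)
    background_m = _check_alignment(model, background)

    bg = background_m.values
    B, k = bg.shape
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(k) for _ in range(n_permutations)])

    base_value = float(predict_raw(model, bg).mean())
    preds = predict_raw(model, samples_m.values)

    # chunk permutations so each predict call sees at most ~_chunk_rows rows
    per_perm_rows = k * B
    perms_per_chunk = max(1, _chunk_rows // per_perm_rows)

    contributions = np.zeros((samples_m.n_subjects, k))
    for s_idx in range(samples_m.n_subjects):
        x = samples_m.values[s_idx]
        phi = np.zeros(k)
        for start in range(0, n_permutations, perms_per_chunk):
            chunk = perms[start:start + perms_per_chunk]
            P = len(chunk)
            # stage j of permutation p: background rows with features
            # chunk[p, :j+1] replaced by the sample's values
            mats = np.broadcast_to(bg, (P, k, B, k)).copy()
            for p in range(P):
                for j in range(k):
                    mats[p, j:, :, chunk[p, j]] = x[chunk[p, j]]
            stage_preds = predict_raw(model, mats.reshape(-1, k))
            stage_means = stage_preds.reshape(P, k, B).mean(axis=2)
            prev = np.concatenate(
                [np.full((P, 1), base_value), stage_means[:, :-1]], axis=1
            )
            marginals = stage_means - prev
            for p in range(P):
                phi[chunk[p]] += marginals[p]
        contributions[s_idx] = phi / n_permutations

    return AttributionResult(
        base_value=base_value,
        contributions=contributions,
        feature_names=list(model.feature_names),
        background_size=B,
        estimator="sampling",
        n_permutations=n_permutations,
        seed=seed,
        sample_values=samples_m.values.copy(),
        predictions=preds,
    )


def exact_shapley(
    model: FittedModel, sample: np.ndarray, background: FeatureMatrix
) -> np.ndarray:
    """Exact Shapley values by exhaustive subset enumeration (k <= 12).

    The value of a coalition S is the mean prediction over background rows
    with the features in S replaced by the sample's values; contributions are
    the classical weighted average of marginal gains and satisfy additivity
    exactly.
    """
    background_m = _check_alignment(model, background)
    bg = background_m.values
    B, k = bg.shape
    if k > 12:
        raise ValueError(f"exact enumeration limited to 12 features, got {k}")
    sample = np.asarray(sample, dtype=float).reshape(k)

    n_masks = 1 << k
    coalition_value = np.empty(n_masks)
    rows = np.empty((n_masks * B, k))
    for mask in range(n_masks):
        block = bg.copy()
        for j in range(k):
            if mask >> j & 1:
                block[:, j] = sample[j]
        rows[mask * B:(mask + 1) * B] = block
    preds = predict_raw(model, rows).reshape(n_masks, B).mean(axis=1)
    coalition_value[:] = preds

    weights = [factorial(s) * factorial(k - s - 1) / factorial(k) for s in range(k)]
    phi = np.zeros(k)
    for mask in range(n_masks):
        size = bin(mask).count("1")
        for j in range(k):
            if not mask >> j & 1:
                phi[j] += weights[size] * (
                    coalition_value[mask | (1 << j)] - coalition_value[mask]
                )
    return phi


def attribute_exact(
    model: FittedModel, samples: FeatureMatrix, background: FeatureMatrix
) -> AttributionResult:
    """Exact-oracle attributions for every row of ``samples`` (k <= 12)."""
    samples_m = _check_alignment(model, samples)
    background_m = _check_alignment(model, background)
    base_value = float(predict_raw(model, background_m.values).mean())
    contributions = np.stack([
        exact_shapley(model, samples_m.values[i], background_m)
        for i in range(samples_m.n_subjects)
    ])
    return AttributionResult(
        base_value=base_value,
        contributions=contributions,
        feature_names=list(model.feature_names),
        background_size=background_m.n_subjects,
        estimator="exact",
        n_permutations=0,
        seed=0,
        sample_values=samples_m.values.copy(),
        predictions=predict_raw(model, samples_m.values),
    )


def importance_ranking(attr: AttributionResult) -> list[tuple[str, float]]:
    """Features by descending mean |contribution|; ties keep input order."""
    imp = np.abs(attr.contributions).mean(axis=0)
    order = np.argsort(-imp, kind="stable")
    return [(attr.feature_names[j], float(imp[j])) for j in order]


def dependence_curve(
    attr: AttributionResult, feature: str, raw_values: np.ndarray
) -> np.ndarray:
    """(raw value, contribution) pairs sorted by raw value, no aggregation."""
    if feature not in attr.feature_names:
        raise KeyError(f"feature {feature!r} not attributed")
    raw_values = np.asarray(raw_values, dtype=float)
    if raw_values.shape[0] != attr.contributions.shape[0]:
        raise ValueError("raw_values length does not match samples")
    j = attr.feature_names.index(feature)
    order = np.argsort(raw_values, kind="stable")
    return np.column_stack([raw_values[order], attr.contributions[order, j]])


def _line_sse(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, sse). Vertical-degenerate
    x (single distinct value) falls back to a flat line at the mean."""
    if np.ptp(x) == 0:
        inter = float(y.mean())
        return 0.0, inter, float(np.sum((y - inter) ** 2))
    slope, inter = np.polyfit(x, y, 1)
    resid = y - (slope * x + inter)
    return float(slope), float(inter), float(resid @ resid)


def fit_changepoint(pairs: np.ndarray) -> ChangepointFit:
    """Exhaustive two-segment fit of a dependence curve.

    Every observed distinct raw value except the two at each edge is tried as
    the breakpoint (left segment: x <= candidate); each side gets its own
    least-squares line and the SSE-minimizing candidate wins. Ties go to the
    larger breakpoint: an exact knot sample fits both adjacent candidates
    equally well, and the larger one places it on the left-inclusive segment,
    consistent with the x <= breakpoint convention. The single-line SSE is
    reported for comparison.
    """
    pairs = np.asarray(pairs, dtype=float)
    x, y = pairs[:, 0], pairs[:, 1]
    distinct = np.unique(x)
    if distinct.size < 6:
        raise ValueError("need at least 6 distinct raw values")
    candidates = distinct[2:-2]

    _, _, sse_linear = _line_sse(x, y)
    best = None
    for c in candidates:
        left = x <= c
        ls, li, lsse = _line_sse(x[left], y[left])
        rs, ri, rsse = _line_sse(x[~left], y[~left])
        sse = lsse + rsse
        if best is None or sse <= best[0] + 1e-12:
            best = (sse, c, ls, li, rs, ri)
    sse, c, ls, li, rs, ri = best
    return ChangepointFit(
        breakpoint=float(c), left_slope=ls, right_slope=rs,
        left_intercept=li, right_intercept=ri,
        sse=float(sse), sse_linear=float(sse_linear),
    )


def subgroup_importance(
    attr: AttributionResult, raw_values: np.ndarray, threshold: float
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Importance rankings for samples at or below vs above ``threshold``.

    ``raw_values`` is the unscaled splitting feature (typically the expanded
    ATXN3 allele), aligned with the attributed samples.
    """
    raw_values = np.asarray(raw_values, dtype=float)
    if raw_values.shape[0] != attr.contributions.shape[0]:
        raise ValueError("raw_values length does not match samples")
    le = raw_values <= threshold
    if not le.any():
        raise ValueError("subgroup at or below threshold is empty")
    if le.all():
        raise ValueError("subgroup above threshold is empty")

    def _rank(mask: np.ndarray) -> list[tuple[str, float]]:
        imp = np.abs(attr.contributions[mask]).mean(axis=0)
        order = np.argsort(-imp, kind="stable")
        return [(attr.feature_names[j], float(imp[j])) for j in order]

    return _rank(le), _rank(~le)


def personalized_explanation(attr: AttributionResult, sample_index: int) -> dict:
    """Additive decomposition of one sample's prediction.

    Entries are sorted by |contribution| descending; the final prediction is
    base_value plus the contribution sum (equal to the model prediction for
    the exact estimator, approximate for the sampler).
    """
    n = attr.contributions.shape[0]
    if not 0 <= sample_index < n:
        raise IndexError(f"sample index {sample_index} out of range [0, {n})")
    contrib = attr.contributions[sample_index]
    order = np.argsort(-np.abs(contrib), kind="stable")
    return {
        "sample_index": int(sample_index),
        "base_value": float(attr.base_value),
        "features": [
            {
                "name": attr.feature_names[j],
                "raw_value": float(attr.sample_values[sample_index, j]),
                "contribution": float(contrib[j]),
            }
            for j in order
        ],
        "final_prediction": float(attr.base_value + contrib.sum()),
        "model_prediction": float(attr.predictions[sample_index]),
    }
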