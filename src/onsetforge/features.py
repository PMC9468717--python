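"""Allele-derived features, pairwise crosses and Pearson screening.

Each locus contributes four variables — the shorter allele A1, the longer
allele A2, their difference D = A2 - A1 and mean M = (A1 + A2)/2 — giving 40
candidate predictors over the 10 polyglutamine loci. Gene-gene interaction is
represented by feature crosses: element-wise products of two distinct original
features (C(40, 2) = 780 crosses, 820 features total). Candidate screens use
the Pearson correlation of each feature with the AAO, with two-sided p-values
from the exact t transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LOCI, VARIABLES, Cohort

logger = logging.getLogger(__name__)

#: Canonical names of the 40 original features, loci-major.
ORIGINAL_FEATURES: tuple[str, ...] = tuple(
    f"{gene}-{var}" for gene in LOCI for var in VARIABLES
)


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature: an original ``LOCUS-VAR`` or a cross ``P1*P2``."""

    name: str
    kind: str  # "original" | "cross"
    parents: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("original", "cross"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind == "cross":
            if len(self.parents) != 2 or self.parents[0] == self.parents[1]:
                raise ValueError(f"cross {self.name!r} needs 2 distinct parents")
            if self.name != f"{self.parents[0]}*{self.parents[1]}":
                raise ValueError(f"cross name {self.name!r} does not match parents")


@dataclass
class FeatureMatrix:
    """Subjects x features values with an AAO target vector."""

    subject_ids: list[str]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray  # (n_subjects, n_features)
    target: np.ndarray  # (n_subjects,) AAO in years

    def __post_init__(self) -> None:
        n, k = self.values.shape
        if len(self.subject_ids) != n or len(self.target) != n:
            raise ValueError("row dimensions inconsistent")
        if len(self.descriptors) != k:
            raise ValueError("feature dimensions inconsistent")
        names = self.feature_names
        if len(set(names)) != len(names):
            raise ValueError("feature names are not unique")
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.target)):
            raise ValueError("non-finite values in matrix")

    @property
    def feature_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in matrix") from None
        return self.values[:, j]

    def restrict(self, names: list[str]) -> "FeatureMatrix":
        """Sub-matrix with the given features, in the given order."""
        idx = []
        all_names = self.feature_names
        for name in names:
            if name not in all_names:
                raise KeyError(f"feature {name!r} not in matrix")
            idx.append(all_names.index(name))
        return FeatureMatrix(
            subject_ids=list(self.subject_ids),
            descriptors=[self.descriptors[j] for j in idx],
            values=self.values[:, idx].copy(),
            target=self.target.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df["aao"] = self.target
        return df


@dataclass
class CorrelationTable:
    """Per-feature Pearson r against AAO with two-sided p and sample size."""

    features: list[str]
    r: np.ndarray
    p: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if not (len(self.features) == len(self.r) == len(self.p)):
            raise ValueError("column lengths inconsistent")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| exceeds 1")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "r": self.r, "p": self.p, "n": self.n}
        )


@dataclass
class StepRecord:
    """One step of a selection trace."""

    step: int
    feature: str | None
    n_candidates: int
    cv_r2: float | None = None
    improvement: float | None = None
    accepted: bool = True


#: Valid feature-optimization method identifiers.
METHODS: tuple[str, ...] = (
    "correlation",
    "crossing_correlation",
    "crossing_correlation_rfe",
    "crossing_correlation_stepsvm",
)


@dataclass
class SelectionResult:
    """Outcome of a feature-optimization method."""

    method: str
    selected: list[str]
    trace: list[StepRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate features in selection")


def derive_features(cohort: Cohort) -> FeatureMatrix:
    """Build the 40-feature matrix (A1, A2, D, M per locus) with AAO target."""
    for s in cohort.subjects:
        missing = [g for g in LOCI if g not in s.alleles]
        if missing:
            raise ValueError(f"subject {s.subject_id} missing loci {missing}")
        for g, (a1, a2) in s.alleles.items():
            if int(a1) != a1 or int(a2) != a2:
                raise ValueError(f"subject {s.subject_id}: non-integer allele at {g}")

    n = len(cohort)
    cols = np.empty((n, len(ORIGINAL_FEATURES)), dtype=float)
    descriptors = []
    j = 0
    for gene in LOCI:
        a1 = cohort.allele_array(gene, 0).astype(float)
        a2 = cohort.allele_array(gene, 1).astype(float)
        for var, vals in (
            ("A1", a1), ("A2", a2), ("D", a2 - a1), ("M", (a1 + a2) / 2.0)
        ):
            cols[:, j] = vals
            descriptors.append(
                FeatureDescriptor(f"{gene}-{var}", "original", (gene, var))
            )
            j += 1
    return FeatureMatrix(
        subject_ids=[s.subject_id for s in cohort.subjects],
        descriptors=descriptors,
        values=cols,
        target=cohort.aao,
    )


def cross_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Append one cross per unordered pair of distinct original features.

    k originals yield k(k-1)/2 crosses (k(k+1)/2 features total). Cross
    values are products of the raw, unscaled parent columns; names use the
    canonical parent order ``P1*P2`` with P1 earlier in the input order.
    """
    for d in matrix.descriptors:
        if d.kind != "original":
            raise ValueError(f"input must contain only originals, got {d.name!r}")

    k = matrix.n_features
    names = matrix.feature_names
    n_cross = k * (k - 1) // 2
    values = np.empty((matrix.n_subjects, k + n_cross), dtype=float)
    values[:, :k] = matrix.values
    descriptors = list(matrix.descriptors)
    j = k
    for i1 in range(k):
        for i2 in range(i1 + 1, k):
            values[:, j] = matrix.values[:, i1] * matrix.values[:, i2]
            descriptors.append(
                FeatureDescriptor(
                    f"{names[i1]}*{names[i2]}", "cross", (names[i1], names[i2])
                )
            )
            j += 1
    return FeatureMatrix(
        subject_ids=list(matrix.subject_ids),
        descriptors=descriptors,
        values=values,
        target=matrix.target.copy(),
    )


def correlate(matrix: FeatureMatrix) -> CorrelationTable:
    """Pearson r of every feature against the AAO target.

    p-values are two-sided, from t = r * sqrt((n-2) / (1-r^2)) on n-2
    degrees of freedom. Constant features have undefined r and are excluded
    from the table with a logged warning.
    """
    n = matrix.n_subjects
    if n < 3:
        raise ValueError("correlation requires at least 3 subjects")
    y = matrix.target
    sy = y.std()
    if sy == 0:
        raise ValueError("target has zero variance")

    X = matrix.values
    sx = X.std(axis=0)
    constant = sx == 0
    if constant.any():
        for name in np.array(matrix.feature_names)[constant]:
            logger.warning("feature %s is constant; excluded from correlation table",
                           name)
    keep = ~constant
    Xk = X[:, keep]
    r = ((Xk - Xk.mean(axis=0)) * (y - y.mean())[:, None]).mean(axis=0) / (
        Xk.std(axis=0) * sy
    )
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return CorrelationTable(
        features=[str(s) for s in np.array(matrix.feature_names)[keep]],
        r=r,
        p=np.clip(p, 0.0, 1.0),
        n=n,
    )


def select_by_correlation(
    table: CorrelationTable,
    p_max: float,
    r_min_abs: float | None = None,
    method: str = "correlation",
) -> SelectionResult:
    """Select features with ``p < p_max`` and, if given, ``|r| > r_min_abs``.

    Both inequalities are strict; the selection is ordered by descending |r|
    with ties broken by table order.
    """
    if not 0 <= p_max <= 1:
        raise ValueError("p_max must be in [0, 1]")
    if r_min_abs is not None and not 0 <= r_min_abs <= 1:
        raise ValueError("r_min_abs must be in [0, 1]")
    mask = table.p < p_max
    if r_min_abs is not None:
        mask &= np.abs(table.r) > r_min_abs
    idx = np.flatnonzero(mask)
    order = idx[np.argsort(-np.abs(table.r[idx]), kind="stable")]
    selected = [table.features[j] for j in order]
    trace = [StepRecord(step=0, feature=None, n_candidates=len(table.features))]
    return SelectionResult(method=method, selected=selected, trace=trace)
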