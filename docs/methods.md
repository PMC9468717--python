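# Methods

## Synthetic cohort generator

Real SCA3/MJD cohorts with per-locus CAG genotypes are not public, so every
experiment here runs on synthetic cohorts whose statistical shape matches the
published descriptive statistics of a 997-subject Chinese SCA3/MJD cohort.

**Alleles.** For each of the 10 polyglutamine loci the two repeat counts are
drawn independently from normal distributions truncated to the published
min/max (± 0.5 repeat) and rounded to integers, then sorted so A1 ≤ A2.
Defaults (`cohort.DEFAULT_GENE_SPECS`) reproduce the published per-locus
means, SDs and ranges, e.g. ATXN3 A2 = 71.80 ± 3.32 repeats on 61–80.
Limitations of this scheme, by construction:

- no cross-locus correlation (only marginal summaries are published; a
  configuration hook could carry a copula later);
- at loci where the two allele distributions overlap (e.g. ATXN2), sorting
  biases the post-sort marginals relative to the configured moments —
  moment-recovery tests therefore assert on ATXN3, whose allele ranges do
  not overlap;
- published tables report small negative allele differences at some loci
  (e.g. ATXN7-D minimum −2), which is inconsistent with A2 being the longer
  allele; the generator enforces A1 ≤ A2 and does not reproduce that
  anomaly. The CSV reader, by contrast, accepts A1 > A2 rows and reorders
  them with a warning.

**Age at onset.** The noise-free expectation is piecewise linear in the
expanded ATXN3 allele a₂ with a knot at 68 repeats,

    μ = 78.81 − 0.5·min(a₂, 68) − 2.5·max(a₂ − 68, 0) + Σ c·(f₁·f₂),

plus optional planted interaction products of named derived features and
Gaussian noise (SD 6.98 y), clamped to [5, 70] years (clamping is logged;
at the defaults it affects ≪1% of subjects). The intercept and noise SD were
calibrated analytically against the integer distribution of a₂ so the
generated cohort has mean AAO 35.0 and SD 10.2 years; the implied
AAO/CAGexp correlation is ≈ −0.73, matching the published univariate screen
(−0.719). The flatter slope below 68 encodes the observation that onset
depends only weakly on short expansions; the knot doubles as ground truth
for changepoint-recovery experiments.

## Feature engineering and screens

Derived variables (D, M) satisfy M ± D/2 = A2/A1 exactly; tests assert these
identities. Crosses are products of *raw* feature values (standardization
happens inside model fitting); Pearson screening is scale-invariant, so this
ordering does not affect the screens. Self-products are excluded — 780 =
C(40, 2) unordered distinct pairs. Screen thresholds are strict inequalities
(p < threshold, |r| > threshold), with p-values from the exact two-sided
t-transform on n − 2 degrees of freedom. Constant features are excluded from
correlation tables with a logged warning. All screens and selections are
computed on the training split only, to avoid leakage into the test metrics;
whole-cohort screening can be emulated by passing the full cohort as the
training argument.

## Wrapper selectors

Both wrapper selectors score candidate subsets by the mean R² of a fixed
support-vector regressor (RBF kernel, C = 1, ε = 0.1, γ = "scale") over a
k-fold assignment drawn once per run and reused for every candidate, so
score differences reflect features rather than fold noise. Settings are
deliberately not tuned inside the selection loop: fixed settings keep
candidate comparisons fair and bound the cost. Ties everywhere break toward
canonical feature order (loci-major, A1/A2/D/M within locus; crosses follow
their first parent).

**StepSVM** seeds with the best single feature — evaluating all singletons
subsumes hard-coding the expanded allele as the start, and on any cohort
with a dominant CAGexp effect they coincide — then greedily adds the best-
scoring feature while the gain stays ≥ 0.001 (CV-R² units) and the set is
under 30 features. **RFE** ranks by refitting a linear SVR and dropping the
smallest-|coefficient| feature each round, then picks the nested subset with
the best CV R² (ties to the smaller subset).

**Known limitation — spurious additions on noise.** The greedy step takes
the maximum of many noisy CV scores, so on a pure-noise target single
spurious additions above the 0.001 bar occur in a sizeable minority of
seeds: the bar is far below the CV noise floor at any realistic cohort size.
Growth still stalls quickly (most seeds stop within two features; the cap is
never approached) and no spurious run reaches a CV R² resembling real
signal. This selection bias is inherent to forward stepwise selection with a
small improvement threshold, not a property of this implementation.

**Identifiability of planted crosses.** A cross of two high-mean variables,
c·f₁·f₂ with f̄ᵢ ≫ sd(fᵢ), is nearly additive — c·(f̄₂·f₁ + f̄₁·f₂) plus a
small centered product — so many sibling crosses sharing a parent are
statistically equivalent proxies, and "recover the exact planted name" is
then ill-posed: the greedy legitimately selects an equivalent basis. The
recovery study therefore plants ATXN7-D × ATXN2-D, whose parents have
near-zero means: the planted signal is a genuine interaction, no proxy
passes the |r| > 0.2 gate, and exact-name recovery is well defined. Study
conditions: 800 subjects, expanded-allele slope −2.2 y/repeat, interaction
coefficient −1.7 (contribution SD ≈ 3.5 y), noise SD 2.0 y, 2-fold scoring,
4-feature cap (`studies.py`); one replicate ≈ 8 s on one CPU.

## Model zoo

Estimator internals are delegated to scikit-learn and xgboost; the package
owns restriction to the selected features, standardization with training
statistics (applied to every algorithm, including trees, for a single
scaling convention), the cross-validated grid search maximizing R² (10
folds by default), refitting on the full training split, and determinism
from a single seed. Default grids span the ranges a practitioner would scan
at n ≈ 1,000: penalty strengths 10⁻² – 10 for the penalized linear models,
elastic-net mixing {0.2, 0.5, 0.8}, Huber thresholds {1.35, 2, 5}, K ∈
{3, 5, 7, 11}, SVR C ∈ {0.1, 1, 10} with ε ∈ {0.05, 0.1, 0.5}, 200/500
trees, XGBoost depths {3, 5} at learning rates {0.05, 0.1}, and one- or
two-layer perceptrons (L-BFGS, ReLU) with L2 ∈ {10⁻⁴, 10⁻³}. All grids are
overridable; replicate studies use single-point grids because they compare
feature sets, not hyperparameters.

## Evaluation

Train size is ⌊0.8 n⌋ by non-repetitive random sampling (997 → 797/200).
Test metrics: R² = 1 − SS_res/SS_tot, MAE, RMSE, MedianAE, and strict-
inequality error bands (|e| < 5, |e| > 10; boundary errors fall in the
middle band, so the three bands partition the samples). The test set is also
partitioned at ATXN3 CAGexp ≤ 68 vs > 68 — one model is fitted and evaluated
piecewise; no piecewise models are fitted. Subsets too small for metrics
(< 2 subjects or constant AAO) are reported as missing with a warning rather
than aborting the comparison.

## Shapley explanation layer

Contributions are reported in years on the prediction scale, with raw
(pre-standardization) feature values attached for interpretation. The
estimator is permutation sampling: for each random feature ordering,
features switch one at a time from background-row values to the explained
sample's values, and each marginal is averaged over the full background
sample (default 100 training rows); the base value is the mean background
prediction. The estimator is unbiased and model-agnostic (it covers the
perceptron and SVR best models); its error shrinks as permutations grow,
and an exact 2^k enumeration oracle (k ≤ 12) provides the reference —
additivity is exact for the oracle and holds to sampling tolerance for the
estimator.

The dependence-curve changepoint fit searches every observed distinct raw
value (excluding two at each edge) as a candidate knot, fits least-squares
lines on each side (left segment inclusive: x ≤ knot), and keeps the
SSE-minimizing candidate; ties break toward the larger candidate, which
places an exact knot sample on the left-inclusive segment. The search is
exhaustive because the domain is small (integer repeats, 61–80); a
two-segment fit can never exceed the single-line SSE, and near-equality of
the two flags "no changepoint".

## Numerical and testing notes

- All randomness flows from explicit integer seeds (`numpy` Generators);
  pipeline stages derive their seeds from one root seed via `SeedSequence`,
  so partial re-runs match full runs, and identical configurations produce
  byte-identical text artifacts.
- Replicate-study sizes used by the test suite: 50 recovery seeds (with the
  R² comparison on the first 25), 100 changepoint replicates, 200
  moment-recovery draws; the acceptance script uses 10 recovery seeds and
  30 changepoint replicates. Together the suite runs in roughly 12 minutes
  on one CPU.
- Zero-variance features are rejected at model fitting (the scaler would be
  undefined) but tolerated in selectors, where they simply never win.
- Cohort CSVs store AAO via `repr`, and the dependence-curve TSV reader uses
  round-trip float parsing, so serialization is bit-exact.
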