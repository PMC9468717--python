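"""Explain a fitted onset model with Shapley values.

Permutation-sampling Shapley attribution decomposes each subject's predicted
onset (in years) into per-feature contributions around the background-mean
prediction. From the attributions we derive the global importance ranking,
the dependence of the expanded-ATXN3 contribution on the raw repeat length
(with a fitted segmentation point), and a personalized per-subject record.
"""

import numpy as np

from onsetforge import SimConfig, SplitSpec, simulate_cohort, split_cohort
from onsetforge import models as model_zoo
from onsetforge.evaluate import build_feature_set
from onsetforge.explain import (
    attribute,
    dependence_curve,
    fit_changepoint,
    importance_ranking,
    personalized_explanation,
)
from onsetforge.features import FeatureMatrix, cross_features, derive_features
from onsetforge.models import ModelConfig

cohort = simulate_cohort(SimConfig(n_subjects=600, seed=5))
train, _ = split_cohort(cohort, SplitSpec(seed=5))
originals = derive_features(train)

sel = build_feature_set(originals, originals, "correlation")
model = model_zoo.fit(
    ModelConfig("SVM", grid={"C": [1.0, 10.0], "epsilon": [0.1]}, cv_folds=5),
    originals, sel,
)

rng = np.random.default_rng(5)


def take(fm, idx):
    return FeatureMatrix([fm.subject_ids[i] for i in idx],
                         list(fm.descriptors), fm.values[idx].copy(),
                         fm.target[idx].copy())


background = take(originals, np.sort(rng.choice(len(train), 60, replace=False)))
samples = take(originals, np.sort(rng.choice(len(train), 150, replace=False)))
attr = attribute(model, samples, background, n_permutations=32, seed=5)

print(f"base value (expected predicted AAO): {attr.base_value:.1f} years")
print("feature importance (mean |contribution| in years):")
for name, value in importance_ranking(attr)[:5]:
    print(f"  {name:12s} {value:.2f}")

pairs = dependence_curve(attr, "ATXN3-A2", samples.column("ATXN3-A2"))
cp = fit_changepoint(pairs)
print(f"\nATXN3-A2 dependence: slope {cp.left_slope:.2f} y/repeat below "
      f"{cp.breakpoint:.0f} repeats, {cp.right_slope:.2f} above "
      f"(two-segment SSE {cp.sse:.1f} vs single-line {cp.sse_linear:.1f})")

record = personalized_explanation(attr, int(np.argmax(attr.predictions)))
print(f"\nsubject with the latest predicted onset "
      f"({record['final_prediction']:.1f} years):")
for entry in record["features"][:3]:
    sign = "+" if entry["contribution"] >= 0 else ""
    print(f"  {entry['name']:12s} raw {entry['raw_value']:5.1f}  "
          f"{sign}{entry['contribution']:.2f} y")
# The expanded allele dominates the ranking, its contribution falls steeply
# only above the segmentation point, and each personalized record sums to
# the subject's model prediction.
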