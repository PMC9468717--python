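"""Compare feature-optimization methods and regression algorithms.

Fits one model per (method, algorithm) pair, then scores each on the full
test set and on the two expanded-allele subsets (ATXN3 CAGexp <= 68 vs > 68)
with six metrics: R², MAE, RMSE, MedianAE and the proportions of subjects
predicted within 5 / off by more than 10 years.
"""

from onsetforge import SimConfig, SplitSpec, simulate_cohort, split_cohort
from onsetforge.evaluate import run_comparison
from onsetforge.models import ModelConfig
from onsetforge.selection import StepSVMConfig, SVRParams

cohort = simulate_cohort(SimConfig(n_subjects=600, seed=11))
train, test = split_cohort(cohort, SplitSpec(seed=11))

result = run_comparison(
    train, test,
    methods=["correlation", "crossing_correlation_stepsvm"],
    algorithms=["LR", "HR", "SVM"],
    stepsvm_config=StepSVMConfig(n_folds=2, max_features=4, fold_seed=11,
                                 base_learner=SVRParams(tol=1e-2)),
    model_configs={
        "LR": ModelConfig("LR", cv_folds=5),
        "HR": ModelConfig("HR", grid={"epsilon": [1.35, 2.0]}, cv_folds=5),
        "SVM": ModelConfig("SVM", grid={"C": [1.0, 10.0], "epsilon": [0.1]},
                           cv_folds=5),
    },
    seed=11,
)

frame = result.report.to_frame()
full = frame[frame.subset == "full_test"]
print(full[["method", "model", "r2", "mae", "rmse", "median_ae",
            "prop_lt5", "prop_gt10"]].round(3).to_string(index=False))
print("\nbest (algorithm, method) by full-test R²:", result.report.best)
# With no planted interaction the two feature sets perform similarly; the
# expanded ATXN3 allele carries nearly all the predictable signal, and R²
# is capped by the generator's noise floor (~0.5 at these settings).
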