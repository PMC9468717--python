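import numpy as np
import pytest

from onsetforge.features import FeatureDescriptor, FeatureMatrix, SelectionResult


def make_matrix(X, y, names=None, ids=None) -> FeatureMatrix:
    """Wrap plain arrays as a FeatureMatrix of 'original' features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    if ids is None:
        ids = [f"s{i}" for i in range(X.shape[0])]
    descriptors = [FeatureDescriptor(n, "original", ("synthetic", n)) for n in names]
    return FeatureMatrix(list(ids), descriptors, X.copy(), y.copy())


def select_all(matrix: FeatureMatrix) -> SelectionResult:
    return SelectionResult("correlation", list(matrix.feature_names))


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort drawn with the default study statistics."""
    from onsetforge.cohort import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(n_subjects=400, seed=20240915))
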