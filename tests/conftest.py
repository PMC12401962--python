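import numpy as np
import pytest

from lcen.data import FeatureMatrix, standardize_features
from lcen.simulate import make_worked_example, simulate_cohort


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort reused by training-level tests."""
    return simulate_cohort(n=200, d_x=20, d_y=9, k=4, seed=3)


def standardized(features):
    return FeatureMatrix(
        standardize_features(features.values),
        features.modality_blocks,
        features.subject_ids,
        features.column_names,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
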