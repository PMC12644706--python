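import numpy as np
import pytest

from breathprint import (
    CohortConfig,
    generate_cohort,
    prepare_features,
)
from breathprint.preprocess import sensor_blocks

PLANTED = ("TGS2602", "TGS2620", "MQ2", "MQ135")


@pytest.fixture(scope="session")
def default_cohort():
    """The default 28 healthy / 18 cancer synthetic cohort, seed 0."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return prepare_features(default_cohort)


@pytest.fixture(scope="session")
def default_blocks(default_features):
    return sensor_blocks(default_features.feature_names)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
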