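import numpy as np
import pytest
from hypothesis import settings

from wristmood.dataset_model import FAST_SVM
from wristmood.pipeline import build_dataset, day_feature_table, preprocess_day
from wristmood.synthetic_data import make_fixture

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def separable3():
    return make_fixture("separable3", seed=7)


@pytest.fixture(scope="session")
def separable3_preprocessed(separable3):
    return [preprocess_day(d) for d in separable3.days]


@pytest.fixture(scope="session")
def separable3_tables(separable3_preprocessed):
    return [day_feature_table(p) for p in separable3_preprocessed]


@pytest.fixture(scope="session")
def separable3_dataset(separable3):
    return build_dataset(separable3.days)


@pytest.fixture(scope="session")
def null_dataset():
    participant = make_fixture("null", seed=11)
    return build_dataset(participant.days)


@pytest.fixture(scope="session")
def collision():
    return make_fixture("collision", seed=3)


@pytest.fixture(scope="session")
def fast_svm():
    return FAST_SVM
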