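import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import caresig
from caresig.simulate import GeneratorConfig, default_class_specs

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ALL_LABELS = [s.label for s in default_class_specs()]


@pytest.fixture(scope="session")
def class_specs():
    return {s.label: s for s in default_class_specs()}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_counts(n_per_class: int = 6) -> dict[str, int]:
    return {label: n_per_class for label in ALL_LABELS}


@pytest.fixture(scope="session")
def small_dataset():
    """54 records (6 per class), moderate noise — shared read-only."""
    cfg = GeneratorConfig(class_counts=small_counts(6), seed=7)
    return caresig.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    from caresig.evaluate import extract_feature_arrays

    return extract_feature_arrays(small_dataset)
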