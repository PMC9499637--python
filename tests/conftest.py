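import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mbfuse.feature_table import FeatureTable
from mbfuse.synthetic_data import default_study_params, generate_study

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """4 samples x 4 features; grand total 100, engineered prevalences."""
    data = pd.DataFrame(
        {
            "f1": [24, 24, 24, 24],   # total 96, prevalence 1.0
            "f2": [1, 1, 1, 0],       # total 3, prevalence 0.75
            "f3": [1, 0, 0, 0],       # total 1, prevalence 0.25
            "f4": [0, 0, 0, 0],       # total 0, prevalence 0
        },
        index=[f"s{i}" for i in range(1, 5)],
    )
    return FeatureTable(data)


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic study shared by read-only tests."""
    return generate_study(default_study_params(seed=11))
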