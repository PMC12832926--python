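import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cardiopso.cohort import CohortConfig, generate_cohort
from cardiopso.schema import DEFAULT_SCHEMA

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_cohort():
    """A 400-patient synthetic cohort with the default planted signal."""
    table, truth = generate_cohort(CohortConfig(n_patients=400, seed=11))
    return table, truth


@pytest.fixture(scope="session")
def strong_cohort():
    """A wide-margin cohort: large effects, little logit noise, so any
    sane classifier separates it well."""
    config = CohortConfig(
        n_patients=400,
        informative_features=("ca", "thal", "cp", "oldpeak"),
        effect_sizes={"ca": 8.0, "thal": 8.0, "cp": 8.0, "oldpeak": 8.0},
        noise_scale=0.05,
        seed=23,
    )
    table, truth = generate_cohort(config)
    return table, truth


@pytest.fixture
def tiny_table():
    """A hand-written 6-row conforming table."""
    return pd.DataFrame(
        {
            "age": [54.0, 61.0, 45.0, 54.0, 70.0, 33.0],
            "sex": [1.0, 0.0, 1.0, 1.0, 0.0, 1.0],
            "cp": [0.0, 2.0, 1.0, 0.0, 3.0, 2.0],
            "trestbps": [130.0, 140.0, 120.0, 130.0, 150.0, 110.0],
            "chol": [250.0, 230.0, 199.0, 250.0, 300.0, 180.0],
            "restecg": [0.0, 1.0, 0.0, 0.0, 2.0, 1.0],
            "fbs": [0.0, 1.0, 0.0, 0.0, 1.0, 0.0],
            "thalach": [150.0, 120.0, 170.0, 150.0, 110.0, 180.0],
            "exang": [0.0, 1.0, 0.0, 0.0, 1.0, 0.0],
            "oldpeak": [1.0, 2.5, 0.0, 1.0, 3.1, 0.2],
            "slope": [1.0, 2.0, 0.0, 1.0, 2.0, 1.0],
            "ca": [0.0, 2.0, 0.0, 0.0, 3.0, 1.0],
            "thal": [0.0, 2.0, 1.0, 0.0, 2.0, 0.0],
            "target": [0.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        },
        columns=list(DEFAULT_SCHEMA.column_names),
    )
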