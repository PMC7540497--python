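import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import enwas

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def smoking_records():
    """Parent/child conditional-question pair: ever smoked? / still smoke?"""
    parent = enwas.VariableRecord(
        name="ever_smoked", domain="lifestyle_life_events",
        var_type=enwas.UNORDERED,
        values=pd.Series(["No", "Yes", "Yes", np.nan, "Yes", "No"]),
        levels=["No", "Yes"],
    )
    child = enwas.VariableRecord(
        name="still_smokes", domain="lifestyle_life_events",
        var_type=enwas.ORDERED,
        values=pd.Series([np.nan, "Yes", "No", np.nan, np.nan, np.nan]),
        levels=["No", "Yes"],
        parent="ever_smoked", parent_gate="Yes",
    )
    return parent, child


@pytest.fixture
def small_spec():
    """A compact synthetic cohort exercising every harmonization path."""
    return enwas.SyntheticSpec(
        n_subjects=300,
        domains=(
            ("parental_health", 6),
            ("family_rearing", 5),
            ("sociodemographic", 4),
        ),
        n_conditional_pairs=2,
        n_dont_know=3,
        seed=11,
    )


@pytest.fixture
def small_cohort(small_spec):
    return enwas.generate(small_spec)
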