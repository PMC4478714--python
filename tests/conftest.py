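import warnings

import numpy as np
import pandas as pd
import pytest

from surveyfuse import (
    FusionSpec,
    SurveyTable,
    VariableSchema,
    generate_population,
    make_fusion_scenario,
)
from surveyfuse.synthetic import PopulationParams, clinical_fusion_spec

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def toy_schema():
    return [
        VariableSchema("gender", "common", "categorical", ("Female", "Male"),
                       codes={"1": "Female", "2": "Male"}),
        VariableSchema("age", "common", "continuous", units="years"),
        VariableSchema("bp", "specific", "continuous", units="mmHg"),
        VariableSchema("status", "specific", "categorical", ("No", "Yes")),
    ]


@pytest.fixture
def toy_spec():
    return FusionSpec(("gender", "age"), ("bp", "status"))


@pytest.fixture
def toy_donor(toy_schema):
    df = pd.DataFrame(
        {
            "gender": ["Female", "Male", "Female", "Male", "Female", "Male"],
            "age": [25.0, 40.0, 60.0, 35.0, 50.0, 70.0],
            "bp": [110.0, 125.0, 140.0, 120.0, 135.0, 150.0],
            "status": ["No", "No", "Yes", "No", "Yes", "Yes"],
        },
        index=[f"d{i}" for i in range(6)],
    )
    return SurveyTable(df, toy_schema)


@pytest.fixture
def toy_recipient(toy_schema):
    df = pd.DataFrame(
        {
            "gender": ["Male", "Female", "Female"],
            "age": [41.0, 26.0, 61.0],
            "bp": [np.nan] * 3,
            "status": [np.nan] * 3,
        },
        index=["r0", "r1", "r2"],
    )
    return SurveyTable(df, toy_schema)


@pytest.fixture(scope="session")
def small_scenario():
    """A small but realistic synthetic fusion scenario (donor ~260 rows)."""
    params = PopulationParams(n=2000)
    population, truth = generate_population(params, seed=11)
    donor, recipient, hidden = make_fusion_scenario(population, 0.13, seed=12)
    return {
        "params": params,
        "population": population,
        "donor": donor,
        "recipient": recipient,
        "hidden": hidden,
        "spec": clinical_fusion_spec(),
    }
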