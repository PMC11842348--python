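import numpy as np
import pandas as pd
import pytest

from qole.scoring import default_schema, score_dataframe, filter_analysis_population
from qole.synthetic import CohortConfig, generate_cohort, make_stable_flag


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def cohort(schema):
    """Default synthetic four-trial cohort, one fixed seed for the session."""
    return generate_cohort(CohortConfig(seed=11), schema)


@pytest.fixture(scope="session")
def panel(cohort, schema):
    panel = score_dataframe(cohort, schema)
    panel, _ = filter_analysis_population(panel)
    return panel


@pytest.fixture(scope="session")
def stable(cohort):
    return make_stable_flag(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def complete_responses(schema, level="best"):
    """All 27 scored items at their best or worst raw value."""
    out = {}
    for it in schema.items:
        if it.domain == "GENERAL":
            continue
        if level == "best":
            out[it.item_id] = it.raw_min if it.reverse else it.raw_max
        else:
            out[it.item_id] = it.raw_max if it.reverse else it.raw_min
    return out
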