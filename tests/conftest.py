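import numpy as np
import pytest

from copdtriage.cohort import CohortConfig, generate_cohort
from copdtriage.features import encode_cohort
from copdtriage.panel import default_panel, simulate_panel
from copdtriage.schema import PatientCase, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully realistic cohort shared across tests."""
    cfg = CohortConfig(
        n_design=20, n_candidates=150, n_total=200, n_validation=30, seed=42
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return encode_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_labels(small_cohort, small_features):
    policies = default_panel(9, seed=7)
    return simulate_panel(small_cohort, policies, seed=8, features=small_features)


def make_case(schema, case_id="c1", **overrides) -> PatientCase:
    """A fully populated in-range case, with optional value overrides."""
    values = {}
    for spec in schema:
        if spec.kind == "categorical":
            values[spec.name] = spec.levels[0]
        else:
            lo, hi = spec.range
            values[spec.name] = round(0.5 * (lo + hi), 1)
    values.update(overrides)
    return PatientCase(case_id=case_id, values=values)


@pytest.fixture
def base_case(schema):
    return make_case(schema)
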