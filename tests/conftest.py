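"""Shared fixtures: small constructed tables and fast model settings."""

from __future__ import annotations

import pandas as pd
import pytest

from ehrlift import ModelSpec, RiskFactorSpec, SimulationConfig

FAST_XGB = ModelSpec("xgboost", {"n_estimators": 40, "max_depth": 3})


def make_events(rows):
    """Events frame from (person_id, concept_id, 'YYYY-MM-DD') tuples."""
    df = pd.DataFrame(rows, columns=["person_id", "concept_id", "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def make_persons(rows, **extra_defaults):
    """Persons frame from (person_id, 'birth_date') tuples plus flag columns."""
    df = pd.DataFrame(rows, columns=["person_id", "birth_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    for col, default in {
        "sex": "F",
        "carrier": False,
        "family_history_any": False,
        "family_history_site": False,
        **extra_defaults,
    }.items():
        df[col] = default
    return df


@pytest.fixture
def small_config():
    """A cheap simulation: one cancer type, one carrier factor."""
    return SimulationConfig(
        n_persons=1500,
        cancer_prevalence={"pancreas": 0.05},
        n_concepts=50,
        background_event_rate=2.0,
        rf_specs=[RiskFactorSpec("carrier", "carrier", 0.05, 5.0)],
        seed=42,
    )


@pytest.fixture
def chain_hierarchy():
    return pd.DataFrame(
        {"parent_concept_id": [1, 2], "child_concept_id": [2, 3]}
    )


@pytest.fixture
def diamond_hierarchy():
    return pd.DataFrame(
        {"parent_concept_id": [1, 1, 2, 3], "child_concept_id": [2, 3, 4, 4]}
    )
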