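"""Shared fixtures: a small synthetic cohort and its feature tables.

Session-scoped so the image pipeline runs once; tests treat the cohort and
tables as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import cnvpheno as c
from cnvpheno.workflow import cohort_features


@pytest.fixture(scope="session")
def tiny_geometry():
    return c.CIRRUS_TINY


@pytest.fixture(scope="session")
def fixture_spec(tiny_geometry):
    return c.CohortSpec(
        n_per_class={
            "none": 6,
            "occult": 12,
            "minimally_classic": 6,
            "predominantly_classic": 12,
        },
        geometry=tiny_geometry,
        seed=1234,
    )


@pytest.fixture(scope="session")
def fixture_cohort(fixture_spec):
    return c.generate_cohort(fixture_spec)


@pytest.fixture(scope="session")
def fixture_features(fixture_spec):
    """Feature table from the full pipeline (render -> segment -> extract)."""
    return cohort_features(fixture_spec, segment=True)


@pytest.fixture(scope="session")
def fixture_truth_features(fixture_spec):
    """Feature table computed from the planted ground-truth masks."""
    return cohort_features(fixture_spec, segment=False)


@pytest.fixture(scope="session")
def subtype_dataset(fixture_features):
    X, y = fixture_features
    return c.LabeledDataset.from_labels(
        X, y, ("occult",), ("predominantly_classic",)
    )


@pytest.fixture(scope="session")
def fast_model_config():
    """Small forest for tests where fit count, not fidelity, dominates."""
    return c.ModelConfig("random_forest", {"n_estimators": 50})


@pytest.fixture(scope="session")
def logistic_config():
    return c.ModelConfig("logistic", {}, {"C": [0.1, 1.0]})
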