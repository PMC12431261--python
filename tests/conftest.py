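"""Shared fixtures: toy knowledge graph, planted cohorts, mock backend, and a
session-trained conditional GAN reused by the heavier end-to-end tests."""

from __future__ import annotations

import pytest
from hypothesis import settings, HealthCheck

from qamt.llm_interface import mock_backend
from qamt.synthetic_fixtures import FixtureSpec, make_cohort, make_toy_kg, training_pairs
from qamt.temporal_gan import GANConfig, train_gan

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec() -> FixtureSpec:
    return FixtureSpec()


@pytest.fixture(scope="session")
def toy_kg(spec):
    return make_toy_kg(spec)


@pytest.fixture(scope="session")
def backend(spec, toy_kg):
    return mock_backend(toy_kg, rules=spec.mock_rules(), seed=0)


@pytest.fixture(scope="session")
def cohort200(spec):
    return make_cohort(FixtureSpec(n_patients=200), seed=7)


@pytest.fixture(scope="session")
def cohort500(spec):
    return make_cohort(FixtureSpec(n_patients=500), seed=7)


@pytest.fixture(scope="session")
def condition_schema(spec):
    return spec.condition_schema()


@pytest.fixture(scope="session")
def trained_gan(cohort500, condition_schema):
    """One conditional model trained at the study scale (n=500, 600 epochs),
    shared across the generation-quality tests."""
    pairs = training_pairs(cohort500, condition_schema)
    cfg = GANConfig(n_variables=8, epochs=600, seed=11)
    return train_gan(pairs, cfg)
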