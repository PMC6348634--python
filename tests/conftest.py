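"""Shared fixtures: the worked-example organisms, a classification
context, and a populated canonical registry."""

import pytest
from hypothesis import settings

import domgran as dg
from domgran.classification import ClassificationContext
from domgran.core import FrameworkConfig
from domgran.perspectives import build_default_registry, populate_registry

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cumulative():
    return dg.worked_example("cumulative")


@pytest.fixture(scope="session")
def constitutive():
    return dg.worked_example("constitutive")


@pytest.fixture(scope="session")
def context(cumulative):
    aset, _ = cumulative
    return ClassificationContext(aset, FrameworkConfig("canonical"))


@pytest.fixture(scope="session")
def classifications(context):
    return context.classify_all()


@pytest.fixture(scope="session")
def populated(context, classifications):
    registry = build_default_registry(context.config)
    assignments, warnings = populate_registry(
        registry, context, classifications)
    return registry, assignments, warnings
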