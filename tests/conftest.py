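"""Shared fixtures: small hand-built tables and session-scoped synthetic runs."""

from __future__ import annotations

import numpy as np
import pytest

import microbeta as mb


@pytest.fixture()
def tiny_abundance() -> mb.AbundanceTable:
    return mb.AbundanceTable(("s1", "s2"), ("A", "B"),
                             np.array([[0.2, 0.8], [0.5, 0.5]]),
                             mode="relative")


@pytest.fixture()
def tiny_environment() -> mb.EnvironmentTable:
    return mb.EnvironmentTable(("s1", "s2"), ("pH", "moisture"),
                               np.array([[4.5, 30.0], [6.5, 22.0]]))


@pytest.fixture(scope="session")
def predator_prey_truth() -> mb.SyntheticTruth:
    return mb.simulate_glv_gradient(mb.predator_prey_params())


@pytest.fixture(scope="session")
def predator_prey_result(predator_prey_truth) -> mb.InferenceResult:
    t = predator_prey_truth
    return mb.infer_interactions(t.abundance, t.environment)


@pytest.fixture(scope="session")
def study_truth() -> mb.SyntheticTruth:
    return mb.emulate_study(seed=0)


@pytest.fixture(scope="session")
def study_result(study_truth) -> mb.InferenceResult:
    t = study_truth
    return mb.infer_interactions(t.abundance, t.environment)


@pytest.fixture(scope="session")
def study_result_absolute(study_truth) -> mb.InferenceResult:
    t = study_truth
    return mb.infer_interactions(t.absolute, t.environment)
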