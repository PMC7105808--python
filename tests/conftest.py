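"""Shared fixtures: all test data are generated programmatically."""

import numpy as np
import pytest

from tonguepipe import (AcquisitionProtocol, RunConfig, Scenario,
                        build_paradigm, build_template_library,
                        simulate_subject)
from tonguepipe.pipeline import run_subject


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def paradigm():
    return build_paradigm(seed=0)


@pytest.fixture(scope="session")
def library(protocol):
    return build_template_library(tuple(protocol.grid_shape), protocol.voxel_mm)


@pytest.fixture(scope="session")
def subject42(protocol, paradigm, library):
    """One default synthetic subject (raw, injected trace, ground truth)."""
    return simulate_subject(protocol, paradigm, Scenario(), 42, library)


@pytest.fixture(scope="session")
def result42():
    """Full pipeline result (both branches) for the default subject."""
    return run_subject(RunConfig(seed=42))
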