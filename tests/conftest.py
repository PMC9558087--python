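"""Shared fixtures: layouts, render settings, and one session-wide
calibration set (expensive to build, reused across pipeline and
acceptance tests)."""

import pytest

from agtlc.pipeline import RenderSettings, build_calibration
from agtlc.synthetic_plate import default_layout

#: seed for every stochastic check in the suite
SUITE_SEED = 20220930


@pytest.fixture(scope="session")
def layout4():
    return default_layout(4)


@pytest.fixture(scope="session")
def layout7():
    """Seven lanes: six standards plus the reference lane."""
    return default_layout(7)


@pytest.fixture(scope="session")
def noiseless():
    return RenderSettings().noiseless()


@pytest.fixture(scope="session")
def default_settings():
    return RenderSettings()


@pytest.fixture(scope="session")
def calibration():
    """Full calibration set at default noise, fixed seed."""
    return build_calibration(seed=SUITE_SEED)
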