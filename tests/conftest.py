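"""Shared fixtures: packs are expensive to build, so they are session-scoped.

All fixtures are deterministic; nothing is read from outside the repo.
"""

import numpy as np
import pytest

from actsim.defaults import (
    DEFAULT_TARGETS,
    make_default_pack,
    table1_discharge_ais_spec,
    uncalibrated_default_pack,
)


@pytest.fixture(scope="session")
def uncal_pack():
    """Complete synthetic pack before baseline moment matching."""
    return uncalibrated_default_pack(seed=0)


@pytest.fixture(scope="session")
def calibrated_pack():
    """The default pack calibrated to the published baseline metrics.

    Calibration runs the full replication protocol internally, so this
    fixture dominates suite runtime; every test needing a realistic
    steady-state system shares it.
    """
    return make_default_pack(seed=1)


@pytest.fixture(scope="session")
def table1_spec():
    return table1_discharge_ais_spec()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def baseline_targets():
    return dict(DEFAULT_TARGETS)
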