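"""Shared fixtures: synthetic scenarios and geometry helpers."""

from __future__ import annotations

import numpy as np
import pytest

from drivecrumb import ProfileConfig
from drivecrumb.spatial import LocalProjection
from drivecrumb.synth import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def clean_scenario():
    """One-month corruption-free scenario (session-cached)."""
    return generate_scenario(ScenarioConfig(months=1), seed=7)


@pytest.fixture(scope="session")
def corrupt_scenario():
    """One-month scenario with every corruption mode switched on."""
    cfg = ScenarioConfig(
        months=1, n_zero_crumbs=5, n_duplicate_crumbs=3, n_abandoned_starts=2,
        n_zero_start_trips=2, egypt_outlier=True, defective_device=True)
    return generate_scenario(cfg, seed=11)


@pytest.fixture(scope="session")
def profile_config():
    return ProfileConfig()


@pytest.fixture()
def stl_projection():
    return LocalProjection(38.63, -90.20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
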