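"""Shared fixtures: short scenario recordings sized for unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from ptstroke.calibration import Group
from ptstroke.config import ScenarioConfig
from ptstroke.synth.ephys import generate_ephys

SHORT = dict(pre_pt_min=10.0, post_pt_min=100.0, sampling_hz=100.0)
SHORT_4AP = dict(pre_pt_min=10.0, post_pt_min=90.0, fourap_delay_min=20.0, sampling_hz=100.0)


def short_config(group: Group | str, seed: int) -> ScenarioConfig:
    kwargs = SHORT_4AP if Group(group).has_4ap else SHORT
    return ScenarioConfig(group=Group(group), seed=seed, **kwargs)


@pytest.fixture(scope="session")
def urethane_short():
    """One short urethane recording with ground truth (onset + delayed SDs)."""
    return generate_ephys(short_config(Group.URETHANE, 11))


@pytest.fixture(scope="session")
def ketamine_short():
    """One short ketamine+4-AP recording (SDs and seizures)."""
    return generate_ephys(short_config(Group.KETAMINE_4AP, 11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
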