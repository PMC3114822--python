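import numpy as np
import pytest

import mobilegam
from mobilegam import geometry


@pytest.fixture(scope="session")
def small_ufp_campaign():
    """A short two-shift campaign, enough to fit every model quickly."""
    cfg = mobilegam.preset("ufp_default")
    cfg.n_shifts = 2
    cfg.minutes_per_shift = 100
    return mobilegam.generate_campaign(cfg, seed=7)


@pytest.fixture(scope="session")
def small_ufp_frame(small_ufp_campaign):
    c = small_ufp_campaign
    frame, _ = mobilegam.assemble_frame(
        c.observations, c.traffic, c.weather, c.sessions, c.roads, "ufp")
    return frame


@pytest.fixture(scope="session")
def midsize_ufp():
    """One mid-size campaign + frame (n ~ 2,475) shared by model tests."""
    cfg = mobilegam.preset("ufp_default")
    cfg.n_shifts = 5
    c = mobilegam.generate_campaign(cfg, seed=3)
    frame, _ = mobilegam.assemble_frame(
        c.observations, c.traffic, c.weather, c.sessions, c.roads, "ufp")
    return c, frame


@pytest.fixture
def straight_road():
    return geometry.RoadSource("r", [(0.0, 0.0), (0.0, 100.0)], [0.0, 0.0])


@pytest.fixture
def elevated_road():
    return geometry.RoadSource("b", [(0.0, 0.0), (100.0, 0.0)], [0.0, 40.0])
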