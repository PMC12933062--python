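"""Shared fixtures: one moderately long foraging session and a small
cell population, built once per test run."""

from __future__ import annotations

import numpy as np
import pytest

from placetopo import synthetic as syn


@pytest.fixture(scope="session")
def arena():
    return syn.ArenaSpec()


@pytest.fixture(scope="session")
def fov():
    return syn.FovSpec()


@pytest.fixture(scope="session")
def traj_20min(arena):
    """A 20-min foraging trajectory (enough for stability splits)."""
    return syn.simulate_trajectory(arena, 1200.0, seed=11)


@pytest.fixture(scope="session")
def population_60(arena, fov):
    """60 synthetic cells, all active, no anatomical coupling."""
    return syn.place_field_population(
        60, arena, fov, active_fraction=1.0, seed=21
    )


@pytest.fixture(scope="session")
def place_cell_recording(arena, traj_20min, population_60):
    """One well-behaved place cell's event train on the shared session."""
    return syn.generate_events(population_60[0], traj_20min, seed=31)
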