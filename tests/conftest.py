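"""Shared fixtures: simulation runs are expensive, so the canonical runs
(one per scenario at a fixed seed, plus a bank of short two-system runs)
are computed once per session and shared across test modules.

Sequential runs use a 60x100 grid with dt = 0.1: the pattern wavelength
(~15 length units) spans ~60 cells at that spacing, far above the
resolution floor, and refinement is checked explicitly elsewhere.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from turingbuds import (
    Grid,
    KineticParameters,
    SimulationSchedule,
    SolverSettings,
    run_sequence,
)

hyp_settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
hyp_settings.load_profile("suite")

COARSE_GRID = Grid(n_x=60, n_y=100)
COARSE_SETTINGS = SolverSettings(dt=0.1)
RUN_SEED = 1
SYMMETRY_SEEDS = tuple(range(100, 120))


@pytest.fixture(scope="session")
def default_params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def coarse_grid() -> Grid:
    return COARSE_GRID


@pytest.fixture(scope="session")
def coarse_settings() -> SolverSettings:
    return COARSE_SETTINGS


@pytest.fixture(scope="session")
def full_run():
    """Full consecutive scenario, paper schedule, seed 1."""
    return run_sequence(
        SimulationSchedule(seed=RUN_SEED, scenario="full"), COARSE_GRID, COARSE_SETTINGS
    )


@pytest.fixture(scope="session")
def remove_bud2_run():
    return run_sequence(
        SimulationSchedule(seed=RUN_SEED, scenario="remove_bud2"),
        COARSE_GRID,
        COARSE_SETTINGS,
    )


@pytest.fixture(scope="session")
def horseshoe_run():
    return run_sequence(
        SimulationSchedule(seed=RUN_SEED, scenario="horseshoe"),
        COARSE_GRID,
        COARSE_SETTINGS,
    )


@pytest.fixture(scope="session")
def two_system_runs():
    """Twenty seeds of the first two systems (primary buds + interbud buds)."""
    runs = {}
    for seed in SYMMETRY_SEEDS:
        runs[seed] = run_sequence(
            SimulationSchedule(n_systems=2, durations=(500.0, 1000.0), seed=seed),
            COARSE_GRID,
            COARSE_SETTINGS,
        )
    return runs
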