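"""Shared fixtures: small grids and simulated registers used across tests."""

import numpy as np
import pytest

import backcalc as bc


@pytest.fixture(scope="session")
def toy_grid():
    """5-year grid, everything observed."""
    return bc.YearGrid(2000, 2000, 2004)


@pytest.fixture(scope="session")
def toy_leaving(toy_grid):
    return bc.LeavingSchedule(toy_grid, np.full(5, 0.02), np.full(5, 0.04))


@pytest.fixture(scope="session")
def toy_params(toy_grid):
    h = np.array([400.0, 900.0, 1500.0, 1100.0, 600.0])
    p = np.array([0.10, 0.15, 0.20, 0.25, 0.28])
    return bc.ParameterVector(toy_grid, h, p)


@pytest.fixture(scope="session")
def toy_counts(toy_grid, toy_params, toy_leaving):
    """One simulated register on the toy grid (fixed seed)."""
    treated, _, _ = bc.simulate_counts(toy_params, toy_leaving, np.random.default_rng(7))
    return bc.CountMatrix(toy_grid, np.where(toy_grid.observed_cell_mask(), treated[0], 0))


def coverage_toy():
    """10-year grid with a 3-year pre-window period; moderate cohort sizes.

    Used for bootstrap behaviour and coverage checks.  Truth follows the
    flat-plus-ramp pre-window rule exactly, so the model is well specified.
    """
    grid = bc.YearGrid(1990, 1993, 1999)
    rule = bc.PreObsRule(flat_value=0.05, flat_until=1990, ramp_from=1991)
    T = grid.n_years
    h = np.array([800.0, 1500, 2500, 3500, 4000, 3800, 3000, 2200, 1500, 1000])
    p = np.empty(T)
    obs0 = grid.index(grid.first_obs_year)
    p[obs0:] = np.linspace(0.15, 0.30, T - obs0)
    p[:obs0] = bc.apply_pre_obs_rule(rule, p[obs0], grid)
    leaving = bc.LeavingSchedule(grid, np.full(T, 0.02), np.full(T, 0.04))
    params = bc.ParameterVector(grid, h, p)
    spec = bc.SimulationSpec(grid=grid, params=params, leaving=leaving)
    return spec, rule


@pytest.fixture(scope="session")
def coverage_toy_spec():
    return coverage_toy()
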