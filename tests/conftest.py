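"""Shared fixtures. The expensive session fixtures run the canonical
100-day study conditions (N = 100, dt = 0.01 h, 20-day transient) once and
are shared by the acceptance tests and the ensemble-level property tests."""

import numpy as np
import pytest
from hypothesis import settings

import redoxclocks as rc

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_grid():
    """The canonical study grid: 100 days at dt = 0.01 h, 20-day transient."""
    return rc.SimulationGrid(dt=0.01, t_end=2400.0, transient=480.0)


@pytest.fixture(scope="session")
def goodwin_traj(full_grid):
    return rc.simulate_goodwin(grid=full_grid)


@pytest.fixture(scope="session")
def kc_sweep(full_grid):
    """Coupling sweep over {0, 0.05, 0.10, 0.15}, 5 realizations per cell.

    Feeds the uncoupled period-distribution check (Kc = 0 cells), the
    weak-coupling mean-field period (Kc = 0.05), the plastic-ensemble
    period pulling (Kc = 0.10) and the R0 / amplitude monotonicity
    properties.
    """
    spec = rc.EnsembleSpec(n=100, seed=7)
    return rc.run_coupling_sweep([0.0, 0.05, 0.10, 0.15], spec, full_grid,
                                 n_realizations=5)


@pytest.fixture(scope="session")
def entrained_run(full_grid, goodwin_traj):
    """Weakly coupled ensemble driven by the TTFL at K_TTFL = 0.25."""
    spec = rc.EnsembleSpec(n=100, kc=0.05, k_ttfl=0.25, seed=13)
    return rc.simulate_ensemble(spec, full_grid, drive=goodwin_traj)
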