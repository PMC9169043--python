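"""Shared fixtures: channel verification runs and the standard fistula run.

The expensive fixtures are session-scoped so the Poiseuille channel solves
and the full three-variant pipeline run are computed once and shared between
the module tests and the acceptance suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import fistulaflow as ff
from fistulaflow.network import ResistorParams
from fistulaflow.pipeline import default_config, run_pipeline
from fistulaflow.solver import (FlowSolver, FluidProperties, SolverConfig,
                                extract_wall_shear)

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")


def solve_poiseuille_channel(n_across: int, *, length_mm: float = 64.0,
                             width_mm: float = 8.0, u_mean: float = 0.02,
                             viscosity: float = 0.035, n_steps: int = 800):
    """Run a viscous channel to steady state; return grid, props, cycle.

    The analytic plane-Poiseuille solution holds for any viscosity; a high
    viscosity shortens the transient so steady state is reached quickly.
    """
    grid = ff.build_channel(length=length_mm, width=width_mm,
                            cell_size=width_mm / n_across,
                            outlet_name="out")
    props = FluidProperties(density=1055.0, dynamic_viscosity=viscosity)
    wave = ff.InletWaveform(Q_mean=u_mean * width_mm * 1e-3, pulsatility=1.0)
    cfg = SolverConfig(dt=0.01)
    solver = FlowSolver(grid, props, cfg, wave, {"out": ResistorParams(1e8)})
    for _ in range(n_steps):
        solver.step()
    cycle = solver.advance_cycle()
    return grid, props, wave, cycle


def poiseuille_wss_error(n_across: int) -> tuple[float, float]:
    """(relative WSS error vs 6 mu U / h, max per-step mass residual)."""
    grid, props, wave, cycle = solve_poiseuille_channel(n_across)
    series = extract_wall_shear(cycle, grid, props)
    tawss = np.abs(series.tau).mean(axis=1)
    mid = np.abs(series.x - 48.0) < 6.0       # developed region
    u_mean = 0.02
    exact = 6.0 * props.dynamic_viscosity * u_mean / 0.008
    err = abs(float(tawss[mid].mean()) - exact) / exact
    return err, float(cycle.mass_residual.max())


@pytest.fixture(scope="session")
def poiseuille_errors():
    """WSS errors and mass residuals at 16 and 32 cells across the channel."""
    err16, mass16 = poiseuille_wss_error(16)
    err32, mass32 = poiseuille_wss_error(32)
    return {"err16": err16, "err32": err32,
            "mass16": mass16, "mass32": mass32}


@pytest.fixture(scope="session")
def desk_result():
    """Full three-variant pipeline run on the standard fistula fixture."""
    cfg = default_config()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # washout cap warnings are expected
        result = run_pipeline(cfg)
    assert not result.errors, f"pipeline variants failed: {result.errors}"
    return result


@pytest.fixture(scope="session")
def desk_config():
    return default_config()


@pytest.fixture()
def case1_spec():
    """Published case-1 morphology on the desk-scale grid."""
    return ff.GeometrySpec(D_E=16.3, L_F=130.2, D_MA=40.8, L_A=39.0,
                           cell_size=2.0)
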