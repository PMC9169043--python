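"""Flow solver verification: Poiseuille oracles, conservation, stability."""

import numpy as np
import pytest

import fistulaflow as ff
from fistulaflow.geometry import GeometrySpec, OcclusionMode, \
    build_fistula_geometry
from fistulaflow.network import ResistorParams, WindkesselParams
from fistulaflow.solver import (FlowCycle, FlowSolver, FluidProperties,
                                SolverConfig, check_periodic_convergence,
                                extract_wall_shear)
from conftest import solve_poiseuille_channel


class TestConfigValidation:
    def test_dt_must_divide_period(self):
        cfg = SolverConfig(dt=0.03)
        with pytest.raises(ValueError, match="divide"):
            cfg.steps_per_cycle(1.0)
        assert SolverConfig(dt=0.01).steps_per_cycle(1.0) == 100

    def test_fluid_properties_must_be_positive(self):
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0)


class TestPoiseuille:
    def test_centerline_velocity_is_three_halves_mean(self,
                                                      poiseuille_errors):
        grid, props, wave, cycle = solve_poiseuille_channel(16,
                                                            n_steps=800)
        i = int(grid.nx * 0.75)
        u_max = cycle.u[-1][i, :].max()
        assert u_max == pytest.approx(1.5 * 0.02, rel=0.02)

    def test_wall_shear_within_three_percent_at_16_cells(self,
                                                         poiseuille_errors):
        assert poiseuille_errors["err16"] < 0.03

    def test_refinement_improves_wall_shear_error_threefold(
            self, poiseuille_errors):
        assert poiseuille_errors["err32"] <= poiseuille_errors["err16"] / 3.0

    def test_mass_conserved_every_step(self, poiseuille_errors):
        assert poiseuille_errors["mass16"] < 0.005
        assert poiseuille_errors["mass32"] < 0.005


class TestWallShearExtraction:
    def test_zero_flow_gives_zero_shear(self):
        grid = ff.build_channel(length=16, width=8, cell_size=1.0)
        props = FluidProperties()
        ns = 4
        cycle = FlowCycle(
            times=0.01 * np.arange(1, ns + 1),
            u=np.zeros((ns, grid.nx + 1, grid.ny)),
            v=np.zeros((ns, grid.nx, grid.ny + 1)),
            p=np.zeros((ns, grid.nx, grid.ny)),
            inlet_flux=np.zeros(ns), port_flux={}, mass_residual=np.zeros(ns))
        series = extract_wall_shear(cycle, grid, props)
        np.testing.assert_array_equal(series.tau, 0.0)

    def test_opposite_channel_walls_have_opposite_signs(self):
        grid, props, wave, cycle = solve_poiseuille_channel(16, n_steps=400)
        series = extract_wall_shear(cycle, grid, props)
        mid = np.abs(series.x - 48.0) < 6.0
        bottom = mid & (series.y < 4.0)
        top = mid & (series.y > 4.0)
        assert (series.tau[bottom, -1] > 0).all()
        assert (series.tau[top, -1] < 0).all()
        np.testing.assert_allclose(np.abs(series.tau[bottom, -1]).mean(),
                                   np.abs(series.tau[top, -1]).mean(),
                                   rtol=1e-6)

    def test_pulsatile_low_womersley_shear_tracks_quasi_steady(self):
        # alpha^2 = (h/2)^2 w / nu ~ 0.03 at this viscosity: quasi-steady
        width = 0.008
        grid = ff.build_channel(length=48, width=8, cell_size=0.5,
                                outlet_name="out")
        props = FluidProperties(density=1055.0, dynamic_viscosity=3.5)
        u_mean = 0.02
        wave = ff.InletWaveform(Q_mean=u_mean * width, pulsatility=2.0)
        cfg = SolverConfig(dt=0.0025)
        solver = FlowSolver(grid, props, cfg, wave,
                            {"out": ResistorParams(1e8)})
        solver.advance_cycle()
        solver.advance_cycle()
        cycle = solver.advance_cycle()
        series = extract_wall_shear(cycle, grid, props)
        mid = (np.abs(series.x - 36.0) < 4.0) & (series.y < 4.0)
        tau_num = series.tau[mid].mean(axis=0)
        q_t = ff.evaluate_inlet_flow(wave, cycle.times)
        tau_qs = 6.0 * props.dynamic_viscosity * (q_t / width) / width
        rel = np.abs(tau_num - tau_qs) / tau_qs.max()
        assert rel.max() < 0.05


class TestPeriodicConvergence:
    def _cycle(self, u_scale):
        ns, nx, ny = 3, 4, 2
        rng_vals = np.arange(ns * (nx + 1) * ny, dtype=float).reshape(
            ns, nx + 1, ny) + 1.0
        return FlowCycle(
            times=0.01 * np.arange(1, ns + 1),
            u=u_scale * rng_vals,
            v=np.zeros((ns, nx, ny + 1)),
            p=np.zeros((ns, nx, ny)),
            inlet_flux=np.zeros(ns), port_flux={}, mass_residual=np.zeros(ns))

    def test_identical_cycles_converged_with_zero_metric(self):
        a, b = self._cycle(1.0), self._cycle(1.0)
        ok, metric = check_periodic_convergence(a, b)
        assert ok and metric == 0.0

    def test_uniform_one_percent_scale_gives_one_percent_metric(self):
        ok, metric = check_periodic_convergence(self._cycle(1.0),
                                                self._cycle(1.01))
        assert metric == pytest.approx(0.01, rel=1e-9)
        assert not ok

    def test_mismatched_snapshot_counts_rejected(self):
        a = self._cycle(1.0)
        b = self._cycle(1.0)
        b.times = b.times[:-1]
        b.u = b.u[:-1]
        b.v = b.v[:-1]
        b.p = b.p[:-1]
        with pytest.raises(ValueError, match="snapshot"):
            check_periodic_convergence(a, b)

    def test_channel_startup_metric_decreases_monotonically(self):
        grid = ff.build_channel(length=32, width=8, cell_size=0.5)
        props = FluidProperties(density=1055.0, dynamic_viscosity=0.0035)
        wave = ff.InletWaveform(Q_mean=0.02 * 0.008, pulsatility=1.0)
        solver = FlowSolver(grid, props, SolverConfig(dt=0.01), wave,
                            {"outlet": ResistorParams(1e8)})
        cycles = [solver.advance_cycle() for _ in range(5)]
        metrics = [check_periodic_convergence(a, b)[1]
                   for a, b in zip(cycles, cycles[1:])]
        assert all(m2 < m1 for m1, m2 in zip(metrics, metrics[1:]))


class TestOccludedFistula:
    def test_dead_end_entrance_net_flux_vanishes_over_a_cycle(self):
        # rigid walls + incompressibility: an occluded fistula stores no
        # net volume, so the cycle-integrated entrance flux is ~0
        spec = GeometrySpec(D_E=16, L_F=48, D_MA=24, L_A=16, L_aorta=96,
                            cell_size=2.0, branches=(),
                            occlusion_mode=OcclusionMode.ANEURYSM_RESERVED)
        grid = build_fistula_geometry(spec)
        props = FluidProperties()
        wave = ff.InletWaveform(Q_mean=1e-3)
        solver = FlowSolver(grid, props, SolverConfig(dt=0.005), wave,
                            {"aortic": WindkesselParams(R_total=2.3171e8)})
        solver.advance_cycle()
        cycle = solver.advance_cycle()
        j_a0 = round(spec.L_F / spec.cell_size)
        i_f0 = round((0.4 * spec.L_aorta - spec.D_E / 2) / spec.cell_size)
        i_f1 = i_f0 + round(spec.D_E / spec.cell_size)
        h = spec.cell_size * 1e-3
        net = float(cycle.v[:, i_f0:i_f1, j_a0].sum()) * h * cycle.dt
        mean_inlet = float(cycle.inlet_flux.mean()) * wave.period
        assert abs(net) < 1e-6 * mean_inlet

    def test_kinetic_energy_bounded_over_100_cycles(self):
        grid = ff.build_channel(length=16, width=8, cell_size=1.0)
        props = FluidProperties()
        wave = ff.InletWaveform(Q_mean=1e-4 * 8e-3)
        solver = FlowSolver(grid, props, SolverConfig(dt=0.01), wave,
                            {"outlet": WindkesselParams(R_total=2e8)})
        energies = []
        for _ in range(100):
            cycle = solver.advance_cycle()
            energies.append(float((cycle.u[-1] ** 2).sum() +
                                  (cycle.v[-1] ** 2).sum()))
        assert np.isfinite(energies).all()
        assert max(energies[50:]) < 2.0 * max(energies[:50])


class TestSolverGuards:
    def test_missing_outlet_model_rejected(self):
        grid = ff.build_channel(length=16, width=8, cell_size=1.0)
        with pytest.raises(ValueError, match="no 0D model"):
            FlowSolver(grid, FluidProperties(), SolverConfig(),
                       ff.InletWaveform(Q_mean=1e-4), {})
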