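"""Inlet waveform and 0D outlet models: closed forms and conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fistulaflow.network import (CoronaryLPNParams, InletWaveform,
                                 NetworkState, ResistorParams,
                                 WindkesselParams, coronary_lpn_step,
                                 evaluate_inlet_flow, intramyocardial_pressure,
                                 make_state, outlet_from_config,
                                 solve_0d_flow_split, windkessel_step)

# published per-outlet total resistances of the second case (Pa s/m^3)
CASE2_R_TOTAL = {
    "aorta": 2.7095e8, "rcaf": 3.7588e8,
    "rca1": 2.7159e10, "rca2": 2.7642e10, "rca3": 2.4753e10,
    "lca1": 2.6813e10, "lca2": 1.9396e10, "lca3": 1.8043e10,
    "lca4": 1.9588e10, "lca5": 2.6045e10,
}


class TestInletWaveform:
    def test_periodicity(self):
        w = InletWaveform(Q_mean=1e-3)
        for t in (0.0, 0.17, 0.5, 0.93):
            assert evaluate_inlet_flow(w, t) == pytest.approx(
                evaluate_inlet_flow(w, t + 1.0))

    def test_unit_pulsatility_is_constant_flow(self):
        w = InletWaveform(Q_mean=2e-3, pulsatility=1.0)
        t = np.linspace(0, 2, 301)
        np.testing.assert_allclose(evaluate_inlet_flow(w, t), 2e-3)

    def test_cycle_mean_matches_q_mean_by_quadrature(self):
        w = InletWaveform(Q_mean=1.3e-3, systolic_fraction=0.4,
                          pulsatility=2.5)
        t = np.linspace(0, 1, 20001)
        mean = np.trapezoid(evaluate_inlet_flow(w, t), t)
        assert mean == pytest.approx(1.3e-3, rel=1e-3)

    @given(st.floats(0.15, 0.6), st.floats(1.0, 3.0),
           st.floats(0.0, 0.999))
    def test_flow_nonnegative_and_peak_is_pulsatility(self, sf, puls, tau):
        w = InletWaveform(Q_mean=1e-3, systolic_fraction=sf, pulsatility=puls)
        assert evaluate_inlet_flow(w, tau) >= 0.0
        assert w.Q_peak == pytest.approx(puls * 1e-3)

    def test_excessive_pulsatility_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            InletWaveform(Q_mean=1e-3, systolic_fraction=0.2, pulsatility=9.0)


class TestWindkessel:
    def test_split_fractions_sum_to_total(self):
        p = WindkesselParams(R_total=2.3171e8)
        assert p.R_p + p.R_d == pytest.approx(p.R_total, rel=1e-12)
        assert p.R_p == pytest.approx(0.09 * p.R_total)

    def test_steady_pressure_is_q_times_r_total(self):
        p = WindkesselParams(R_total=2.3171e8)
        s = make_state(p)
        Q = 1.2e-4
        for _ in range(20000):
            s, P = windkessel_step(p, s, Q, 0.005)
        assert P == pytest.approx(Q * p.R_total, rel=1e-6)

    def test_zero_flow_decay_constant_is_rd_times_c(self):
        # published case-1 aortic R_total with the 0.001 cm^5/dyne compliance
        p = WindkesselParams(R_total=2.3171e8)
        assert p.tau == pytest.approx(0.91 * 2.3171e8 * 1.0e-8)  # ~2.109 s
        s = NetworkState(np.array([5000.0]))
        ts, pcs = [], []
        for _ in range(4000):
            s, _ = windkessel_step(p, s, 0.0, 0.001)
            ts.append(s.t)
            pcs.append(s.values[0])
        slope = np.polyfit(ts, np.log(pcs), 1)[0]
        assert -1.0 / slope == pytest.approx(p.tau, rel=0.005)

    def test_sinusoidal_response_matches_rc_transfer_function(self):
        p = WindkesselParams(R_total=2.3171e8)
        w = 2 * math.pi
        Q0, Qa = 1e-4, 5e-5
        dt = 1.0 / 1000.0
        s = make_state(p, Q_init=Q0)
        n_trans = int(12 * p.tau / dt)
        traj = []
        for k in range(n_trans + 1000):
            t_new = (k + 1) * dt
            q = Q0 + Qa * math.sin(w * t_new)
            s, P = windkessel_step(p, s, q, dt)
            if k >= n_trans:
                traj.append((t_new, P))
        t = np.array([x[0] for x in traj])
        P_num = np.array([x[1] for x in traj])
        H = p.R_d / (1 + 1j * w * p.R_d * p.C)
        P_exact = (Q0 * p.R_d + Qa * np.imag(H * np.exp(1j * w * t)) +
                   p.R_p * (Q0 + Qa * np.sin(w * t)))
        rms = np.sqrt(np.mean((P_num - P_exact) ** 2) /
                      np.mean(P_exact ** 2))
        assert rms < 0.01

    def test_unconditionally_stable_at_dt_equal_period(self):
        p = WindkesselParams(R_total=2.3171e8)
        s = make_state(p, Q_init=1e-4)
        for _ in range(200):
            s, P = windkessel_step(p, s, 1e-4, 1.0)
            assert np.isfinite(P)
        assert P == pytest.approx(1e-4 * p.R_total, rel=1e-6)

    def test_halving_dt_changes_periodic_trace_under_point2_percent(self):
        p = WindkesselParams(R_total=2.3171e8)
        w = InletWaveform(Q_mean=1e-4)

        def periodic_trace(dt):
            s = make_state(p, Q_init=w.Q_mean)
            n = int(round(1.0 / dt))
            for _ in range(30 * n):
                s, _ = windkessel_step(p, s, evaluate_inlet_flow(w, s.t + dt),
                                       dt)
            trace = []
            for _ in range(n):
                s, P = windkessel_step(p, s, evaluate_inlet_flow(w, s.t + dt),
                                       dt)
                trace.append(P)
            return np.array(trace)

        coarse = periodic_trace(0.01)
        fine = periodic_trace(0.005)[1::2]
        rms = np.sqrt(np.mean((coarse - fine) ** 2) / np.mean(fine ** 2))
        assert rms < 0.002

    def test_nonpositive_dt_rejected(self):
        p = WindkesselParams(R_total=1e8)
        with pytest.raises(ValueError, match="dt"):
            windkessel_step(p, make_state(p), 1e-4, 0.0)


class TestCoronaryLPN:
    def test_resistance_split_sums_to_total(self):
        p = CoronaryLPNParams(R_total=6.2281e9)
        assert p.R_a + p.R_am + p.R_v == pytest.approx(p.R_total, rel=1e-9)

    def test_steady_state_matches_symbolic_solve_of_the_odes(self):
        # dP1/dt = 0, d(P2-Pim)/dt = 0 with constant Q and Pim:
        # solve the stated ODE system symbolically and compare
        import sympy as sp

        Q, Ra, Ram, Rv, P1, P2 = sp.symbols("Q Ra Ram Rv P1 P2")
        eqs = [sp.Eq(Q, (P1 - P2) / Ram), sp.Eq((P1 - P2) / Ram, P2 / Rv)]
        sol = sp.solve(eqs, [P1, P2])
        P_sym = sp.simplify(sol[P1] + Q * Ra)

        p = CoronaryLPNParams(R_total=6.2281e9, P_im=lambda t: 2000.0)
        qv = 1e-5
        expected = float(P_sym.subs({Q: qv, Ra: p.R_a, Ram: p.R_am,
                                     Rv: p.R_v}))
        s = make_state(p)
        for _ in range(400000):
            s, P = coronary_lpn_step(p, s, qv, 0.002)
        assert P == pytest.approx(expected, rel=1e-6)
        # for this circuit topology the steady state is the series sum
        assert expected == pytest.approx(qv * p.R_total, rel=1e-12)

    def test_small_cim_limit_recovers_series_resistors(self):
        p = CoronaryLPNParams(R_total=1e9, C_a=1e-14, C_im=1e-14,
                              P_im=lambda t: 0.0)
        s = make_state(p)
        for _ in range(200):
            s, P = coronary_lpn_step(p, s, 2e-5, 0.01)
        assert P == pytest.approx(2e-5 * 1e9, rel=1e-6)

    def test_raising_intramyocardial_pressure_raises_proximal_pressure(self):
        # ramp Pim with flow held fixed: P increases monotonically
        p = CoronaryLPNParams(R_total=6.2281e9,
                              P_im=lambda t: min(t, 1.0) * 8000.0)
        s = make_state(p, Q_init=1e-5)
        ps = []
        for _ in range(100):
            s, P = coronary_lpn_step(p, s, 1e-5, 0.005)
            ps.append(P)
        diffs = np.diff(ps)
        assert (diffs > 0).all()

    def test_intramyocardial_waveform_shape(self):
        assert intramyocardial_pressure(0.9) == 0.0
        peak = intramyocardial_pressure(0.175)
        assert peak == pytest.approx(16e3)
        assert intramyocardial_pressure(0.175, scale=0.5) == \
            pytest.approx(8e3)


class TestFlowSplit:
    def test_two_pure_resistors_current_divider(self):
        w = InletWaveform(Q_mean=1e-4, pulsatility=1.0)
        fr = solve_0d_flow_split(w, [ResistorParams(1e8), ResistorParams(9e8)])
        np.testing.assert_allclose(fr, [0.9, 0.1], atol=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_identical_outlets_split_equally(self, n):
        w = InletWaveform(Q_mean=1e-3)
        fr = solve_0d_flow_split(
            w, [WindkesselParams(R_total=2e8) for _ in range(n)])
        np.testing.assert_allclose(fr, np.full(n, 1.0 / n), atol=1e-9)

    def test_case2_outlet_set_steady_flow_matches_resistor_divider(self):
        w = InletWaveform(Q_mean=1e-4, pulsatility=1.0)
        outs = {k: WindkesselParams(R_total=v)
                for k, v in CASE2_R_TOTAL.items()}
        fr = solve_0d_flow_split(w, outs)
        g = {k: 1.0 / v for k, v in CASE2_R_TOTAL.items()}
        gt = sum(g.values())
        for name in CASE2_R_TOTAL:
            assert fr[name] == pytest.approx(g[name] / gt, abs=0.005)

    def test_fractions_sum_to_one_with_mixed_outlets(self):
        w = InletWaveform(Q_mean=1e-3)
        outs = [WindkesselParams(R_total=2.3171e8),
                WindkesselParams(R_total=6.8721e8),
                CoronaryLPNParams(R_total=6.2281e9),
                CoronaryLPNParams(R_total=1.2908e10)]
        fr = solve_0d_flow_split(w, outs)
        assert fr.sum() == pytest.approx(1.0, abs=0.005)
        assert (fr > 0).all()

    def test_single_outlet_rejected(self):
        w = InletWaveform(Q_mean=1e-3)
        with pytest.raises(ValueError, match="two outlets"):
            solve_0d_flow_split(w, [ResistorParams(1e8)])


class TestConfigParsing:
    def test_rcr_block_with_published_compliance_units(self):
        p = outlet_from_config({"kind": "rcr", "R_total": 2.3171e8,
                                "C_cm5_per_dyne": 0.001})
        assert isinstance(p, WindkesselParams)
        assert p.C == pytest.approx(1.0e-8)

    def test_coronary_block_scales_intramyocardial_pressure(self):
        p = outlet_from_config({"kind": "coronary", "R_total": 6.2281e9,
                                "pim_scale": 0.5})
        assert isinstance(p, CoronaryLPNParams)
        assert p.pim(0.175) == pytest.approx(8e3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown outlet kind"):
            outlet_from_config({"kind": "venous", "R_total": 1e8})
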