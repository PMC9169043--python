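"""Pulsatile inlet waveform and 0D (lumped-parameter) outlet models.

The inlet carries a periodic volumetric flow waveform (period 1 s by default,
a half-sine systolic pulse over a diastolic plateau).  Each outlet is closed by
a 0D model that converts the instantaneous outflow into a pressure:

* ``ResistorParams`` — a pure resistance, P = Q R (verification fixture).
* ``WindkesselParams`` — three-element RCR: proximal resistance R_p = 0.09
  R_total in series with a parallel compliance C / distal resistance
  R_d = 0.91 R_total; used at the aortic outlet.
* ``CoronaryLPNParams`` — a coronary lumped-parameter network
  (R_a — C_a — R_am — C_im — R_v) whose intramyocardial compliance C_im is
  referenced to a time-varying intramyocardial pressure P_im(t), squeezing
  the coronary bed during systole; used at coronary outlets.

All states advance by backward Euler, which for these linear elements yields
an affine relation Q = g P − h between outlet flow and outlet pressure over
one step.  That affine form is what couples the models to both the pure-0D
flow-split solve here and the 2D pressure projection in
:mod:`fistulaflow.solver` (the coupled system stays linear and is solved
exactly, with no relaxation loop).

Units are SI throughout: flow m³/s, pressure Pa, resistance Pa·s/m³,
compliance m³/Pa.  The published compliance 0.001 cm⁵/dyne converts to
1.0e−8 m³/Pa (factor 1e−5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "InletWaveform",
    "evaluate_inlet_flow",
    "intramyocardial_pressure",
    "ResistorParams",
    "WindkesselParams",
    "CoronaryLPNParams",
    "NetworkState",
    "make_state",
    "windkessel_step",
    "coronary_lpn_step",
    "solve_0d_flow_split",
    "outlet_from_config",
]

CM5_PER_DYNE_TO_M3_PER_PA = 1.0e-5
DEFAULT_COMPLIANCE = 0.001 * CM5_PER_DYNE_TO_M3_PER_PA  # = 1.0e-8 m^3/Pa


# ---------------------------------------------------------------------------
# inlet waveform

@dataclass(frozen=True)
class InletWaveform:
    """Periodic inlet flow: half-sine systole over a diastolic plateau.

    ``pulsatility`` is the peak-to-mean ratio; ``systolic_fraction`` the
    fraction of the period occupied by the systolic pulse.  The diastolic
    plateau level is chosen so the cycle mean is exactly ``Q_mean``.
    """

    Q_mean: float                   # m^3/s
    period: float = 1.0             # s
    systolic_fraction: float = 0.35
    pulsatility: float = 3.0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.Q_mean < 0:
            raise ValueError("period must be > 0 and Q_mean >= 0")
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.pulsatility < 1:
            raise ValueError("pulsatility (peak/mean) must be >= 1")
        if self.Q_diastolic < -1e-15 * max(self.Q_mean, 1.0):
            raise ValueError(
                "waveform would go negative: reduce pulsatility or increase "
                "systolic_fraction")

    @property
    def _sine_mean_weight(self) -> float:
        # cycle-mean of the half-sine bump of unit amplitude
        return 2.0 * self.systolic_fraction / math.pi

    @property
    def Q_diastolic(self) -> float:
        w = self._sine_mean_weight
        return (self.Q_mean - w * self.pulsatility * self.Q_mean) / (1.0 - w)

    @property
    def Q_peak(self) -> float:
        return self.pulsatility * self.Q_mean

    def __call__(self, t):
        return evaluate_inlet_flow(self, t)


def evaluate_inlet_flow(w: InletWaveform, t):
    """Flow (m³/s) at time ``t`` (scalar or array); periodic, non-negative."""
    tau = np.mod(np.asarray(t, dtype=float), w.period) / w.period
    qd = w.Q_diastolic
    amp = w.Q_peak - qd
    q = np.where(tau < w.systolic_fraction,
                 qd + amp * np.sin(np.pi * tau / w.systolic_fraction),
                 qd)
    return float(q) if np.isscalar(t) or np.ndim(t) == 0 else q


def intramyocardial_pressure(t, period: float = 1.0,
                             systolic_fraction: float = 0.35,
                             peak: float = 16e3, scale: float = 1.0):
    """Ventricular-shaped intramyocardial pressure (Pa): sin² systolic bump.

    ``scale`` is 1.0 for the left coronary bed, 0.5 for the right.
    """
    tau = np.mod(np.asarray(t, dtype=float), period) / period
    p = np.where(tau < systolic_fraction,
                 scale * peak * np.sin(np.pi * tau / systolic_fraction) ** 2,
                 0.0)
    return float(p) if np.ndim(t) == 0 else p


# ---------------------------------------------------------------------------
# outlet parameter containers

@dataclass(frozen=True)
class ResistorParams:
    """Pure resistive outlet, P = Q R (no state)."""

    R: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("resistance must be positive")

    @property
    def R_total(self) -> float:
        return self.R


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element RCR Windkessel with the 0.09/0.91 proximal/distal split."""

    R_total: float
    C: float = DEFAULT_COMPLIANCE
    proximal_fraction: float = 0.09

    def __post_init__(self) -> None:
        if self.R_total <= 0 or self.C <= 0:
            raise ValueError("R_total and C must be positive")
        if not (0 < self.proximal_fraction < 1):
            raise ValueError("proximal_fraction must lie in (0, 1)")

    @property
    def R_p(self) -> float:
        return self.proximal_fraction * self.R_total

    @property
    def R_d(self) -> float:
        return (1.0 - self.proximal_fraction) * self.R_total

    @property
    def tau(self) -> float:
        """Diastolic decay constant R_d C (s)."""
        return self.R_d * self.C


def _pim_default(t: float) -> float:
    return intramyocardial_pressure(t)


@dataclass(frozen=True)
class CoronaryLPNParams:
    """Coronary lumped-parameter outlet: R_a — C_a — R_am — C_im(P_im) — R_v.

    States are the pressure P1 over C_a and the pressure P2 over C_im; C_im is
    referenced to the intramyocardial pressure waveform ``P_im(t)`` so that
    systolic myocardial contraction impedes coronary inflow.  Venous pressure
    is taken as zero.  Splits of R_total default to 0.32/0.52/0.16
    (arterial / microvascular / venous), standard coronary-LPN practice.
    """

    R_total: float
    arterial_fraction: float = 0.32
    micro_fraction: float = 0.52
    C_a: float = 1.0e-10
    C_im: float = 1.0e-9
    P_im: object = field(default=_pim_default, compare=False)

    def __post_init__(self) -> None:
        if self.R_total <= 0:
            raise ValueError("R_total must be positive")
        if self.C_a <= 0 or self.C_im <= 0:
            raise ValueError("compliances must be positive")
        f_v = 1.0 - self.arterial_fraction - self.micro_fraction
        if min(self.arterial_fraction, self.micro_fraction, f_v) <= 0:
            raise ValueError("resistance fractions must be positive and sum < 1")

    @property
    def R_a(self) -> float:
        return self.arterial_fraction * self.R_total

    @property
    def R_am(self) -> float:
        return self.micro_fraction * self.R_total

    @property
    def R_v(self) -> float:
        return (1.0 - self.arterial_fraction - self.micro_fraction) * self.R_total

    def pim(self, t: float) -> float:
        return float(self.P_im(t))


OutletParams = ResistorParams | WindkesselParams | CoronaryLPNParams


@dataclass
class NetworkState:
    """Internal pressure states (Pa) of one outlet model plus current time."""

    values: np.ndarray
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.values.copy(), self.t)


def make_state(params: OutletParams, t: float = 0.0,
               Q_init: float = 0.0) -> NetworkState:
    """Fresh state, initialized at the steady state for flow ``Q_init``."""
    if isinstance(params, ResistorParams):
        return NetworkState(np.zeros(0), t)
    if isinstance(params, WindkesselParams):
        return NetworkState(np.array([Q_init * params.R_d]), t)
    if isinstance(params, CoronaryLPNParams):
        p2 = Q_init * params.R_v
        p1 = p2 + Q_init * params.R_am
        return NetworkState(np.array([p1, p2]), t)
    raise TypeError(f"unknown outlet params {type(params).__name__}")


# ---------------------------------------------------------------------------
# backward-Euler steps

def _check_dt(dt: float) -> None:
    if not dt > 0:
        raise ValueError("dt must be positive")


def windkessel_step(p: WindkesselParams, state: NetworkState, Q_in: float,
                    dt: float) -> tuple[NetworkState, float]:
    """Advance dP_c/dt = (Q_in − P_c/R_d)/C by one implicit step.

    Returns the new state and the outlet pressure P = P_c + Q_in R_p.
    """
    _check_dt(dt)
    pc = state.values[0]
    pc_new = (pc + dt * Q_in / p.C) / (1.0 + dt / (p.R_d * p.C))
    P = pc_new + Q_in * p.R_p
    return NetworkState(np.array([pc_new]), state.t + dt), P


def coronary_lpn_step(p: CoronaryLPNParams, state: NetworkState, Q_in: float,
                      dt: float) -> tuple[NetworkState, float]:
    """Advance the two-compliance coronary ODEs by one implicit step.

        C_a  dP1/dt        = Q_in − (P1 − P2)/R_am
        C_im d(P2−P_im)/dt = (P1 − P2)/R_am − P2/R_v

    Returns the new state and the proximal pressure P = P1 + Q_in R_a.
    """
    _check_dt(dt)
    p1, p2 = state.values
    t_new = state.t + dt
    dpim = p.pim(t_new) - p.pim(state.t)
    a = dt / (p.C_a * p.R_am)
    b = dt / (p.C_im * p.R_am)
    c = dt / (p.C_im * p.R_v)
    # (1+a) P1' − a P2'        = P1 + dt Q/C_a
    # −b P1' + (1+b+c) P2'     = P2 + dpim
    A = np.array([[1.0 + a, -a], [-b, 1.0 + b + c]])
    rhs = np.array([p1 + dt * Q_in / p.C_a, p2 + dpim])
    p1n, p2n = np.linalg.solve(A, rhs)
    P = p1n + Q_in * p.R_a
    return NetworkState(np.array([p1n, p2n]), t_new), P


def outlet_step(params: OutletParams, state: NetworkState, Q_in: float,
                dt: float) -> tuple[NetworkState, float]:
    """Dispatch on the outlet kind."""
    if isinstance(params, ResistorParams):
        _check_dt(dt)
        return NetworkState(state.values, state.t + dt), Q_in * params.R
    if isinstance(params, WindkesselParams):
        return windkessel_step(params, state, Q_in, dt)
    if isinstance(params, CoronaryLPNParams):
        return coronary_lpn_step(params, state, Q_in, dt)
    raise TypeError(f"unknown outlet params {type(params).__name__}")


def outlet_affine(params: OutletParams, state: NetworkState,
                  dt: float) -> tuple[float, float]:
    """Affine backward-Euler relation Q = g P − h over one step.

    Eliminating the internal states of the implicit step gives outlet flow as
    an affine function of the outlet pressure at the end of the step; ``1/g``
    is the instantaneous (one-step) resistance of the outlet.
    """
    if isinstance(params, ResistorParams):
        return 1.0 / params.R, 0.0
    if isinstance(params, WindkesselParams):
        pc = state.values[0]
        beta = 1.0 + dt / (params.R_d * params.C)
        k = dt / (params.C * beta)
        # P = pc/beta + Q (R_p + k)
        R_eff = params.R_p + k
        return 1.0 / R_eff, pc / (beta * R_eff)
    if isinstance(params, CoronaryLPNParams):
        p1, p2 = state.values
        t_new = state.t + dt
        dpim = params.pim(t_new) - params.pim(state.t)
        a = dt / (params.C_a * params.R_am)
        b = dt / (params.C_im * params.R_am)
        c = dt / (params.C_im * params.R_v)
        A = np.array([[1.0 + a, -a], [-b, 1.0 + b + c]])
        Ainv = np.linalg.inv(A)
        # P1' = Ainv[0] @ (p1 + dt Q/C_a, p2 + dpim) = s0 + m Q
        s0 = Ainv[0, 0] * p1 + Ainv[0, 1] * (p2 + dpim)
        m = Ainv[0, 0] * dt / params.C_a
        # P = P1' + Q R_a = s0 + (m + R_a) Q
        R_eff = m + params.R_a
        return 1.0 / R_eff, s0 / R_eff
    raise TypeError(f"unknown outlet params {type(params).__name__}")


# ---------------------------------------------------------------------------
# pure-0D flow split

def solve_0d_flow_split(waveform: InletWaveform,
                        outlets: list[OutletParams] | dict[str, OutletParams],
                        dt: float | None = None,
                        max_cycles: int = 100,
                        rel_tol: float = 1e-3) -> np.ndarray | dict[str, float]:
    """Cycle-averaged flow fraction of each outlet fed from one pressure node.

    The inlet flow Q(t) splits among the outlets, which all see a common
    upstream pressure P(t).  Each implicit step the affine relations
    Q_i = g_i P − h_i are summed and solved for P such that ΣQ_i = Q(t).
    Cycles repeat until the 0D states change by less than ``rel_tol``
    (relative, cycle to cycle), then one more cycle is integrated for the
    averages.  Fractions sum to 1 (the split is exact by construction).
    """
    named = isinstance(outlets, dict)
    names = list(outlets.keys()) if named else None
    params = list(outlets.values()) if named else list(outlets)
    if len(params) < 2:
        raise ValueError("need at least two outlets for a flow split")
    if dt is None:
        dt = waveform.period / 200.0
    n_steps = max(2, int(round(waveform.period / dt)))
    dt = waveform.period / n_steps

    # start every outlet at the steady resistive split of the mean flow;
    # coronary/RCR charging time constants can reach hundreds of seconds,
    # so a cold start would converge to a spuriously un-charged state
    g_static = np.array([1.0 / p.R_total for p in params])
    q_static = waveform.Q_mean * g_static / g_static.sum()
    states = [make_state(p, 0.0, Q_init=q) for p, q in zip(params, q_static)]

    def run_cycle(states, accumulate: bool):
        q_sums = np.zeros(len(params))
        for k in range(n_steps):
            t0 = states[0].t
            gh = [outlet_affine(p, s, dt) for p, s in zip(params, states)]
            g = np.array([x[0] for x in gh])
            hh = np.array([x[1] for x in gh])
            Q_in = evaluate_inlet_flow(waveform, t0 + dt)
            P = (Q_in + hh.sum()) / g.sum()
            Qs = g * P - hh
            states = [outlet_step(p, s, q, dt)[0]
                      for p, s, q in zip(params, states, Qs)]
            if accumulate:
                q_sums += Qs
        return states, q_sums / n_steps

    history = []
    for cycle in range(max_cycles):
        prev = np.concatenate([s.values for s in states] + [np.zeros(1)])
        states, _ = run_cycle(states, accumulate=False)
        cur = np.concatenate([s.values for s in states] + [np.zeros(1)])
        scale = max(np.abs(cur).max(), 1e-30)
        resid = np.abs(cur - prev).max() / scale
        history.append(resid)
        if resid < rel_tol:
            break
    else:
        raise RuntimeError(
            "0D network did not reach a periodic state within "
            f"{max_cycles} cycles; residual history tail: {history[-5:]}")

    _, q_mean = run_cycle(states, accumulate=True)
    fractions = q_mean / q_mean.sum()
    if named:
        return dict(zip(names, fractions))
    return fractions


# ---------------------------------------------------------------------------
# config parsing

def outlet_from_config(block: dict) -> OutletParams:
    """Build outlet params from a JSON config block.

    ``{"kind": "rcr"|"coronary"|"resistor", "R_total": ..., ...}``; RCR
    compliance may be given as ``C_cm5_per_dyne`` (published units) or
    ``C`` (m³/Pa); coronary blocks accept ``pim_scale`` (1.0 left, 0.5 right).
    """
    kind = block.get("kind", "rcr")
    R = float(block["R_total"])
    if kind == "resistor":
        return ResistorParams(R)
    if kind == "rcr":
        if "C_cm5_per_dyne" in block:
            C = float(block["C_cm5_per_dyne"]) * CM5_PER_DYNE_TO_M3_PER_PA
        else:
            C = float(block.get("C", DEFAULT_COMPLIANCE))
        return WindkesselParams(R_total=R, C=C)
    if kind == "coronary":
        scale = float(block.get("pim_scale", 1.0))
        peak = float(block.get("pim_peak", 16e3))
        period = float(block.get("period", 1.0))
        sf = float(block.get("systolic_fraction", 0.35))

        def pim(t, period=period, sf=sf, peak=peak, scale=scale):
            return intramyocardial_pressure(t, period, sf, peak, scale)

        kw = {}
        for key in ("arterial_fraction", "micro_fraction", "C_a", "C_im"):
            if key in block:
                kw[key] = float(block[key])
        return CoronaryLPNParams(R_total=R, P_im=pim, **kw)
    raise ValueError(f"unknown outlet kind {kind!r}")
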