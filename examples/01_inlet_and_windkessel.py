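"""Pulsatile inlet waveform and a Windkessel RCR outlet, step by step.

Builds the standard cardiac inlet waveform (period 1 s, peak/mean 3) and
drives an aortic three-element Windkessel with it, printing the cycle mean
flow and the periodic pressure range the outlet settles into.
"""

import numpy as np

from fistulaflow import InletWaveform, WindkesselParams, evaluate_inlet_flow
from fistulaflow.network import make_state, windkessel_step

wave = InletWaveform(Q_mean=1.0e-3, period=1.0, systolic_fraction=0.35,
                     pulsatility=3.0)
t = np.linspace(0.0, 1.0, 1001)
q = evaluate_inlet_flow(wave, t)
print(f"inlet flow: mean {np.trapezoid(q, t) * 1e3:.3f} L/s "
      f"(target {wave.Q_mean * 1e3:.3f}), peak {q.max() * 1e3:.3f} L/s, "
      f"diastolic plateau {wave.Q_diastolic * 1e3:.3f} L/s")

# aortic outlet: published case-1 total resistance, 0.09/0.91 split,
# compliance 0.001 cm^5/dyne = 1e-8 m^3/Pa
wk = WindkesselParams(R_total=2.3171e8)
print(f"Windkessel: R_p {wk.R_p:.3e}, R_d {wk.R_d:.3e} Pa s/m^3, "
      f"decay constant R_d C = {wk.tau:.3f} s")

state = make_state(wk, Q_init=wave.Q_mean)
dt = 1e-3
pressures = []
for k in range(25000):  # ~12 decay constants: periodic regime
    t_new = (k + 1) * dt
    state, p = windkessel_step(wk, state, evaluate_inlet_flow(wave, t_new),
                               dt)
    if k >= 24000:
        pressures.append(p)
p = np.array(pressures)
print(f"periodic outlet pressure: {p.min() / 1e3:.1f} - {p.max() / 1e3:.1f} "
      f"kPa (mean {p.mean() / 1e3:.1f} kPa = Q_mean R_total "
      f"{wave.Q_mean * wk.R_total / 1e3:.1f} kPa)")
# The mean pressure equals Q_mean * R_total: the compliance only shapes the
# waveform, the resistances set the operating point.
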