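"""Pure-0D flow split across a published outlet resistance set.

Couples every outlet of the second patient case (aortic RCR plus fistula and
coronary outlets, all as RCR here) to one pressure node fed by the pulsatile
inlet, and prints each outlet's share of the cycle-averaged flow next to the
steady resistor-divider value it should bracket.
"""

from fistulaflow import InletWaveform, WindkesselParams, solve_0d_flow_split

R_TOTAL = {
    "aorta": 2.7095e8, "rcaf": 3.7588e8,
    "rca1": 2.7159e10, "rca2": 2.7642e10, "rca3": 2.4753e10,
    "lca1": 2.6813e10, "lca2": 1.9396e10, "lca3": 1.8043e10,
    "lca4": 1.9588e10, "lca5": 2.6045e10,
}

wave = InletWaveform(Q_mean=1.0e-3, pulsatility=3.0)
outlets = {name: WindkesselParams(R_total=r) for name, r in R_TOTAL.items()}
fractions = solve_0d_flow_split(wave, outlets)

g_total = sum(1.0 / r for r in R_TOTAL.values())
print(f"{'outlet':<8} {'pulsatile %':>12} {'divider %':>10}")
for name in R_TOTAL:
    divider = 100.0 / (R_TOTAL[name] * g_total)
    print(f"{name:<8} {100 * fractions[name]:>12.2f} {divider:>10.2f}")
print(f"sum of fractions: {100 * sum(fractions.values()):.2f}%")
# With pure RCR outlets the cycle-averaged split collapses onto the
# resistor divider; the fistula outlet (rcaf) 'steals' roughly a third of
# the inlet flow from the aorta, which is what occlusion corrects.
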