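"""Closed-form mean-field solution against the ensemble simulation.

At low pairing frequency the bistable efficacy SDE homogenizes to an
Ornstein-Uhlenbeck process with piecewise-constant coefficients, switching at
the threshold-inactivation times.  This script prints the per-pathway switch
fractions U (depressed -> potentiated) and D (potentiated -> depressed) from
both routes at dt = -10 ms.
"""

from calstdp import load_preset
from calstdp.analytic import homogenize, switch_probs
from calstdp.dynamics import SimulationSettings, simulate
from calstdp.protocols import StimulationProtocol

model = load_preset("corticostriatal")
protocol = StimulationProtocol(pattern="pair", dt=-0.010, freq=1.0, n_pairings=100)
settings = SimulationSettings.for_model(model, seed=0, record_per_pairing=True)
res = simulate(model, protocol, settings)

for p in model.pathways:
    phases = homogenize(model, p, protocol)
    print(f"{p.name}: {len(phases)} OU phase(s), boundaries at "
          f"{[round(ph.t_end, 1) for ph in phases[:-1]]} s")
    for n in (13, 40, 74, 100):
        u_a, d_a = switch_probs(phases, model.rho_star, protocol.period, n)
        u_s, d_s = res.uds_at(n)[p.name]
        print(f"  n={n:3d}  U sim {u_s:.3f} / analytic {u_a:.3f}   "
              f"D sim {d_s:.3f} / analytic {d_a:.3f}")
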