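"""Inspect the calcium transient behind one post-pre pairing.

Builds the cortico-striatal calcium trace for a single pairing at
dt = -10 ms, prints the peak levels, the time spent above each plasticity
threshold, and the pairing counts at which the cumulative calcium silences
each LTP mechanism.
"""

from calstdp import load_preset
from calstdp.calcium import inactivation_pairing, trace_from_schedule
from calstdp.protocols import StimulationProtocol, build_schedule

model = load_preset("corticostriatal")
protocol = StimulationProtocol(pattern="pair", dt=-0.010, freq=1.0, n_pairings=100)

single = StimulationProtocol(pattern="pair", dt=-0.010, freq=1.0, n_pairings=1)
trace = trace_from_schedule(build_schedule(single), model.calcium)

print("calcium events (time s, amplitude):", list(zip(trace.times, trace.amplitudes)))
print(f"peak after the second event: {trace.value_at(trace.times[1]):.2f}")
for p in model.pathways:
    for label, theta in (("LTP", p.theta0_p), ("LTD", p.theta0_d)):
        if theta == float("inf"):
            continue
        eta = trace.time_above(theta, (-0.5, 0.5))
        print(f"{p.name} {label} threshold {theta}: {eta * 1000:.2f} ms above per pairing")
for p in model.pathways:
    n = inactivation_pairing(p.mu_p, protocol, model.calcium)
    print(f"{p.name}-LTP inactivates at pairing {n} (mu = {p.mu_p})")
print("One pairing deposits", round((model.calcium.c_pre + model.calcium.c_post)
      * model.calcium.tau_ca, 4), "units of cumulative calcium.")
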