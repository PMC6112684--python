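"""Pharmacological blockade in silico: one signalling pathway at a time.

Blocking a pathway means computing the macroscopic change through the
remaining efficacies only (the total is a product of per-pathway factors).
NMDAR-only plasticity shows post-pre LTP only after ~70 pairings; eCB-only
plasticity shows early post-pre LTP that disappears with pairing count.
"""

from calstdp import load_preset
from calstdp.dynamics import SimulationSettings
from calstdp.experiments import blockade_heatmap, stdp_heatmap

model = load_preset("corticostriatal")
settings = SimulationSettings.for_model(model, seed=0, n_synapses=500)

joint = stdp_heatmap(model, [-0.010], 100, 1.0, settings)
ecb = blockade_heatmap(model, ["eCB"], [-0.010], 100, 1.0, settings)
nmdar = blockade_heatmap(model, ["NMDAR"], [-0.010], 100, 1.0, settings)

print("dt = -10 ms, 1 Hz; total change (1 = no change):")
print("pairings   joint   eCB-only   NMDAR-only")
for n in (13, 40, 75, 100):
    j = joint.data.query("n_pairings == @n").total_change.iloc[0]
    e = ecb.data.query("n_pairings == @n").total_change.iloc[0]
    m = nmdar.data.query("n_pairings == @n").total_change.iloc[0]
    print(f"{n:8d}   {j:.3f}   {e:.3f}      {m:.3f}")
print("(the joint factor is exactly the product of the two blockade runs)")
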