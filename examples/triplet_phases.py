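"""Spike-triplet protocols and their pairing-number phase profiles.

A post-pre-pre triplet (one postsynaptic spike before two presynaptic spikes)
recruits eCB-LTP earlier and more strongly than a spike pair; the resulting
total-change curve vs pairing count is classified into polarity phases
('P' potentiation, 'D' depression) with the deterministic surrogate for
visual inspection.
"""

from calstdp import load_preset
from calstdp.dynamics import SimulationSettings
from calstdp.experiments import classify_phases, run_protocol
from calstdp.protocols import StimulationProtocol

model = load_preset("corticostriatal")
settings = SimulationSettings.for_model(model, seed=0, n_synapses=500)

# dt_i = t_post - t_pre,i, dt1 < dt2 < 0: the post spike leads both pre spikes
protocol = StimulationProtocol(
    pattern="pre_post_pre", dt1=-0.030, dt2=-0.010, freq=1.0, n_pairings=100
)
df = run_protocol(model, protocol, settings)
for n in (10, 40, 60, 100):
    row = df[df.n_pairings == n].iloc[0]
    print(f"{n:3d} triplets: total change {row.total_change:.3f}")
label = classify_phases(df.total_change.to_numpy())
print(f"phase profile: {label.label}, phases start at pairings {label.boundaries}")
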