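"""Non-monotonic plasticity vs the number of pairings (cortico-striatal).

Runs the ensemble simulator at dt = -10 ms (post-pre) and +10 ms (pre-post),
1 Hz, and prints the macroscopic change after 13, 40 and 100 pairings.
Post-pre pairings show early eCB-LTP, a silent stretch once eCB-LTP has
inactivated, and a late NMDAR-LTP; pre-post pairings develop eCB-LTD.
Values are relative synaptic strength (1 = no change).
"""

from calstdp import load_preset
from calstdp.dynamics import SimulationSettings
from calstdp.experiments import classify_phases, run_protocol
from calstdp.protocols import StimulationProtocol

model = load_preset("corticostriatal")
settings = SimulationSettings.for_model(model, seed=0, n_synapses=500)

for dt_ms in (-10, 10):
    protocol = StimulationProtocol(
        pattern="pair", dt=dt_ms / 1000, freq=1.0, n_pairings=100
    )
    df = run_protocol(model, protocol, settings)
    picks = df[df.n_pairings.isin([13, 40, 100])]
    print(f"dt = {dt_ms:+d} ms:")
    for _, row in picks.iterrows():
        print(
            f"  {int(row.n_pairings):3d} pairings: total change "
            f"{row.total_change:.3f} (H_eCB {row.H_eCB:.3f}, H_NMDAR {row.H_NMDAR:.3f})"
        )
    label = classify_phases(df.total_change.to_numpy())
    print(f"  phase profile: {label.label} (phase starts at pairings {label.boundaries})")
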