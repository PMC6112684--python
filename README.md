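# calstdp

Multi-pathway, calcium-based modelling of spike-timing-dependent plasticity
(STDP) with activity-dependent threshold inactivation.

Synapses such as the cortico-striatal one express plasticity through several
signalling pathways at once — an endocannabinoid (eCB) mechanism that can
drive both long-term potentiation (LTP) and depression (LTD), and an
NMDA-receptor (NMDAR) mechanism driving LTP — and the outcome of a pairing
protocol depends not only on the spike timing Δt but on *how many times* and
*how fast* the pairing is repeated.  `calstdp` implements a stochastic
bistable-synapse model of this interplay for computational neuroscientists
who want to simulate pairing/triplet protocols, predict frequency and
pairing-number dependence, or explore alternative pathway architectures.

## The model

Each of *P* pathways carries an individual synaptic efficacy ρ_α ∈ [0, 1]
obeying

    τ dρ_α = [ −ρ_α(1−ρ_α)(ρ_*−ρ_α)
               + γ_α^p (1−ρ_α) Θ(c(t) − θ_α^p)
               − γ_α^d ρ_α     Θ(c(t) − θ_α^d) ] dt
             + σ √(Θ_p + Θ_d) dW_α

where the cubic term makes each efficacy bistable (depressed 0 / potentiated
1 around the unstable midpoint ρ_*), and the LTP/LTD drives switch on while
the shared calcium concentration c(t) exceeds pathway-specific thresholds.
Calcium is a sum of decaying exponentials: each pre/post spike deposits an
impulse (C_pre, delayed by D, or C_post) that relaxes with time constant
τ_Ca.  The thresholds *inactivate* once the cumulative calcium ∫c exceeds a
pathway level μ_α^x (receptor desensitisation / resource depletion), either
abruptly (piecewise model) or smoothly over a sharpness ε (exponential
model).  Gated Gaussian noise (intensity σ, active only while a mechanism is
engaged) lets individual synapses switch stochastically.

An ensemble of N synapses per initial state yields the switch fractions
U_α = P(0→1) and D_α = P(1→0); the macroscopic relative change in synaptic
strength is the product over pathways of a sigmoid readout

    H(U/D) = a + b / (1 + e^{−s(U/D − d)}),   H(0)=LTD*, H(1)=1, H(∞)=LTP*.

At low pairing frequency the gated SDE homogenizes to an Ornstein–Uhlenbeck
process with piecewise-constant coefficients (switching at the inactivation
times), giving closed-form Gaussian switch probabilities — the `analytic`
engine.

## Worked example

```python
# examples/pairing_regimes.py
from calstdp import load_preset
from calstdp.dynamics import SimulationSettings
from calstdp.experiments import run_protocol, classify_phases
from calstdp.protocols import StimulationProtocol

model = load_preset("corticostriatal")
settings = SimulationSettings.for_model(model, seed=0, n_synapses=500)
protocol = StimulationProtocol(pattern="pair", dt=-0.010, freq=1.0, n_pairings=100)
df = run_protocol(model, protocol, settings)
```

prints (post-pre pairings, Δt = −10 ms, 1 Hz):

```
dt = -10 ms:
   13 pairings: total change 3.475 (H_eCB 3.475, H_NMDAR 1.000)
   40 pairings: total change 1.000 (H_eCB 1.000, H_NMDAR 1.000)
  100 pairings: total change 3.475 (H_eCB 1.000, H_NMDAR 3.475)
  phase profile: PP (phase starts at pairings (13, 66))
dt = +10 ms:
  100 pairings: total change 0.550 (H_eCB 0.550, H_NMDAR 1.000)
  phase profile: D (phase starts at pairings (47,))
```

Total change is relative synaptic strength (1 = no change).  The post-pre
curve is biphasic potentiation–potentiation ("PP"): an early eCB-LTP that
vanishes once eCB-LTP inactivates (cumulative calcium μ = 6 ≙ 14 pairings),
a silent stretch, then a late NMDAR-LTP (inactivating at 74 pairings);
pre-post pairings develop eCB-LTD from ~47 pairings on.  The other examples
cover the calcium trace (`calcium_trace.py`), the mean-field solution
(`analytic_vs_simulation.py`), pathway blockade (`pathway_blockade.py`) and
triplet protocols (`triplet_phases.py`).

A thin CLI mirrors the library:

```bash
calstdp simulate --preset corticostriatal --dt -10ms --freq 1 --npairings 100 \
    --seed 7 --out run.csv
calstdp heatmap --preset corticostriatal --engine analytic --out heatmap.csv
```

Presets (`corticostriatal`, `scenario1`–`scenario3` for symmetric
anti-Hebbian LTD architectures, `hebbian_asymmetric`/`hebbian_symmetric`)
ship as editable YAML files; `calstdp.read_config` accepts the same schema
with `ms`/`s` unit suffixes.

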