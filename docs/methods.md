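# Methods

## Model

Each synapse is a bundle of `P` independent pathway efficacies ρ_α sharing
one postsynaptic calcium trace.  The calcium model is linear and solved in
closed form: every spike deposits an exponential impulse (amplitude `c_post`
at postsynaptic spike times, `c_pre` at presynaptic times shifted by the
influx delay `delay_d`, decay `tau_ca`; baseline 0).  All derived
quantities — instantaneous concentration, running integral,
threshold-crossing intervals and the time at which the cumulative calcium
reaches an inactivation level — are evaluated exactly from the event list
(`calstdp.calcium`), never from a grid.

Each efficacy follows the bistable SDE (τ-scaled form)

    τ dρ = [ −ρ(1−ρ)(ρ_*−ρ) + γ^p (1−ρ) A_p(t) − γ^d ρ A_d(t) ] dt
           + σ √(A_p + A_d) dW,

with A_x(t) = 1 while c(t) exceeds the threshold θ^x and that mechanism is
not yet inactivated.  Two threshold models are provided: *piecewise*
(threshold jumps to +∞ once ∫c ≥ μ^x) and *exponential*
(θ^x(t) = θ_0^x + exp((∫c − μ^x)/ε), sharpness ε), the former being the
small-ε limit of the latter and the one used by the closed-form solution.

**Noise convention.**  The noise intensity σ enters the τ-scaled equation on
the same footing as the rates γ, so the efficacy increment per unit time
carries σ/τ: Var[dρ] = (σ/τ)² (A_p + A_d) dt.  This convention is the one
that reproduces the model's characteristic pairing-number regimes with the
shipped parameter sets — the post-pre LTP window opening at 12–13 pairings
and closing near 25, the silent stretch around 40, and the NMDAR-LTP
re-emergence near 70.  A convention with variance larger by a factor τ
(σ/√τ per √time) produces Gaussian tails that leave a few percent of the
depressed-start ensemble potentiated throughout the silent stretch, which
the ratio readout amplifies to maximal LTP and which erases the silent
regime entirely; we therefore reject it.  The homogenized diffusion below
follows the same convention.

## Ensembles and readout

Two ensembles of `n_synapses` efficacies per pathway are integrated, one
started at ρ = 0 and one at ρ = 1, sharing the calcium-driven gates but with
independent noise.  Switch fractions are classified against ρ_*:
U = P(ρ > ρ_* | start 0), D = P(ρ < ρ_* | start 1).  Post-protocol dynamics
are deterministic and preserve the side of ρ_*, so end-of-protocol fractions
equal steady-state fractions.  Per-pairing curves snapshot the same
realization just before each pairing's first calcium event; successive
counts are therefore correlated, which mimics following one preparation
through a protocol and does not bias the per-count marginals.

The macroscopic change is ∏_α H(U_α/D_α) with the sigmoid H pinned by
H(0) = LTD*, H(1) = 1, H(∞) = LTP*; the coefficient closed forms require
exp(s) > Δ = (LTP*−LTD*)/(LTP*−1), which the parameter types enforce.
Degenerate fractions are fixed by the pinning conditions: U = D = 0 gives
factor 1 (an unstimulated synapse must be neutral), D = 0 < U gives LTP*.
Ratios are formed from fractions, so the ensemble size cancels.  Pathway
blockade restricts the product to a subset of pathways; the joint factor is
exactly the product of the single-pathway factors.

## Numerical scheme

Fixed-step Euler–Maruyama over the window `t_start..t_end` with `n_iter`
steps (preset defaults: window −1..101 s; 102 000 steps, i.e. ≈1 ms, for the
cortico-striatal and classical-Hebbian sets; 204 000 for the scenario sets;
N = 1000 per initial state).  Because the gates are deterministic functions
of calcium they are precomputed once per run.  For the piecewise threshold
model the per-step gate value is the *fractional occupancy* of the step by
the exact closed-form crossing intervals, cut at the exact
cumulative-calcium crossing time; this removes the step-quantisation bias in
the integrated drive per pairing (up to one step per threshold crossing),
which matters because several of the model's transitions sit within a few
ensemble standard deviations of ρ_*.  The exponential threshold model
samples its time-varying threshold at step midpoints.  Noise is applied with
amplitude (σ/τ)·√(A_p+A_d)·√dt on steps with open gates; ρ is not clipped —
the cubic drift restores excursions.  Reproducibility: one `SeedSequence`
per run spawns a child generator per pathway; identical settings give
bit-identical results, and a numba-accelerated kernel (used when available)
is bit-identical to the numpy reference path.

Step-halving at the defaults changes U and D by less than Monte-Carlo
resolution away from transition counts; exactly at a stochastic transition
(e.g. the pairing at which a mean crosses ρ_*) the fractions are intrinsically
sensitive to any perturbation, including the noise stream.

## Closed-form mean-field solution

When calcium relaxes essentially completely between pairings (enforced as a
residual below 10⁻⁶ of one pattern's amplitude; violated at a few tens of
Hz, where the solver refuses and points to the simulator), the gated linear
drift homogenizes over a period T = 1/F.  With η^x the exact time above
threshold θ^x per pairing and Γ^x = γ^x η^x / T, each pathway is an OU
process dρ = (αρ + β)dt + √s₂ dW with

    α = −(Γ^p + Γ^d)/τ,   β = Γ^p/τ,   s₂ = σ² (η^p + η^d) / (T τ²),

piecewise constant between the inactivation times t_x = n_x T (n_x the
pairing count at which ∫c reaches μ^x, i.e. ⌈μ^x / ((ΣC)·τ_Ca)⌉ in the
fully-relaxing regime).  Mean and variance propagate in closed form across
any number of phases (the propagation is invariant under phase subdivision),
and the switch probabilities are the Gaussian tails at t = nT:
U = ½(1 + erf((m₀−ρ_*)/√(2v))), D analogously from the potentiated start.
Zero variance degenerates to a point mass.

**Finite-ensemble floor.**  Gaussian tails are never exactly zero, but an
experiment with N synapses cannot register switch probabilities below ~1/N;
without a floor the readout turns probabilities of order 10⁻²⁰ into maximal
LTP (ratio → ∞) while the matched simulation reports factor 1.  The analytic
engine therefore treats fractions below 1/(2N) as zero before forming U/D
ratios.  This is a reporting convention of this package, chosen to make the
two engines describe the same N-synapse experiment.

The linearization neglects the cubic term; along trajectories that linger at
mid-range ρ for tens of seconds this biases the mean by roughly 0.01
(towards the starting basin), visible only where a mean sits within a few
ensemble standard deviations of ρ_*.

## Protocols and experiments

Protocols are deterministic: `pair` (Δt = t_post − t_pre; negative means
post leads), and the triplet patterns `pre_post_pre` (two pre, one post,
Δt_i = t_post − t_pre,i, Δt₁ < Δt₂) and `post_pre_post` (one pre, two post,
Δt_i = t_post,i − t_pre, Δt₁ > Δt₂); pre spike #1 of repetition k anchors at
k/F (the anchor only shifts the time origin).  Frequency sweeps fold Δt into
(−1/(2F), 1/(2F)] — the protocol is periodic in Δt — and report mean/sd over
30 independent replicates by default.  Triplet maps run the two-pre family
above the Δt₁ = Δt₂ diagonal and the two-post family below it; coincident
spikes are excluded by the protocol invariants.  Frequencies above 40 Hz
trigger a model-validity warning.

Curve reading uses explicit band constants (`calstdp.experiments`): LTP
means total change > 1.15, LTD < 0.90, "no plasticity" within [0.90, 1.10].
`classify_phases` is a deterministic surrogate for by-eye phase labelling:
mark counts outside 1 ± delta (default 0.1) with their polarity, absorb
polarity runs shorter than `min_run` (default 5 pairings), merge
same-polarity runs separated by gaps shorter than `min_run`, and concatenate
the surviving polarities (e.g. "PP", "PD", "PPD"); both knobs are exposed
and recorded in CLI metadata.

## Parameter presets

Six presets ship as YAML (times accept `ms`/`s` suffixes; internally
everything is seconds — the seconds convention is forced by the
cumulative-calcium arithmetic: one cortico-striatal pairing deposits
(7 + 17.1)·0.018 = 0.4338, so μ = 6 and μ = 32 correspond to pairings 14
and 74):

- `corticostriatal` — eCB (LTP γ 290, θ 6, μ 6; LTD γ 250, θ 13.5) and NMDAR
  (LTP-only γ 50, θ 5.8, μ 32) pathways; τ = 165 s, σ = 1,
  readout LTP* = 3.475, LTD* = 0.55, slope 0.7.
- `scenario1`–`scenario3` — one- and two-pathway architectures constrained to
  symmetric anti-Hebbian LTD at 100 pairings / 1 Hz, distinguishable by
  their pairing-number and frequency responses; scenario 3's pre/post delay
  is set to 10 ms, matching scenario 2 (the two share all calcium
  parameters).
- `hebbian_asymmetric` / `hebbian_symmetric` — classical single-pathway
  Hebbian STDP parameterizations with monotonic establishment.

All pathways share one readout parameterization; per-pathway readouts are
supported structurally but no preset uses them.

## What the synthetic protocols do and do not show

All inputs are deterministic spike schedules; there are no Poisson trains,
no stochastic calcium, no spatial compartments or receptor kinetics.
Passing tests therefore certify the mathematical behaviour of this model
class under idealized stimulation, not quantitative predictions for any
particular preparation.  Within the model, several documented behaviours sit
on parameter knife edges: with the scenario presets the depression band at
100 pairings / 1 Hz spans roughly |Δt| ≲ 10–18 ms (beyond that the
homogenized LTD drift Γ^d falls below the τ·ln2/100 needed to cross ρ_*, or
inactivates a couple of pairings before crossing), and at 30 Hz the LTP of
scenario 2 weakens when the two calcium impulses nearly coincide (a taller
but narrower transient spends less total time above the LTP threshold).
Tests that probe these edges report them as found.

## Limitations

- The mean-field engine covers low pairing frequencies only; high-frequency
  regimes use the simulator.
- The bistable well makes the model rigid: no significant plasticity below
  ~10 pairings, and timing-independent LTP requires several tens of Hz.
- The exponential threshold model has no closed-form solution here and is
  compared to the piecewise model only qualitatively.
- With gated noise and sharp thresholds, ensemble fractions change abruptly
  near transition pairing counts; quantities read exactly at a transition
  are sensitive to discretisation and seed.
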