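# Methods

## The model cell

The compartmental model is a deliberately reduced stand-in for a cortical
fast-spiking interneuron: a 15 µm × 15 µm cylindrical soma with five
unbranched dendrites, 200 µm long and 1.5 µm in diameter, axial resistivity
172 Ω·cm, specific capacitance 1.0 µF/cm². Sections are split into equal
compartments of at most 10 µm (102 compartments in total); halving the
compartment length moves the steady somatic potential by far less than the
0.05 mV bound the tests enforce. The geometry admits the synapse placement
used throughout: five sites 96–100 µm from the soma, 1 µm apart, on one
dendrite. SWC morphologies can be substituted for the built-in geometry;
only soma (type 1) and basal-dendrite (type 3) samples are honored.

Membrane mechanisms, all subthreshold:

| mechanism | form | defaults | units |
|---|---|---|---|
| K⁺ leak | ohmic, e_K = −107 mV | fitted | S/cm² |
| Na⁺ leak | ohmic, e_Na = +53 mV | fitted | S/cm² |
| Kir | g·m(V), m(V) = 1/(1+e^{(V−v_half)/k}) | v_half −85 mV, k 12 mV (v_half refit in calibration) | S/cm² |
| synapse | weight·(e^{−t/τ_d} − e^{−t/τ_r})/norm, e_syn = 0 | τ_r 0.5 ms; weight, τ_d fitted | µS |
| background noise | OU excitatory + inhibitory conductances | τ_e 2.7 ms, τ_i 10.5 ms, e_exc 0, e_inh −75 mV; means/SDs from the point-conductance literature, jointly rescaled | µS |

The Kir open fraction is instantaneous (no gating kinetics): the channel's
millisecond-scale kinetics are far faster than the 10–100 ms phenomena of
interest, and the data constrain only the steady rectification. Scaling the
"5HT-sensitive K⁺ pool" by (1−f) means scaling the K⁺ leak and Kir
densities together (a Kir-only mode exists); the study's pharmacology
attributes the suppressed current to Kir, but its model scaled every K⁺
mechanism, and the split between ohmic and rectifying components is refit
here anyway.

## Numerics

The cable equation is integrated by backward Euler on the voltage with all
conductances frozen at the previous step (Kir at the previous voltage,
synapses and noise at the new time), dt = 0.025 ms. Compartments are stored
parent-before-child, so one reverse sweep eliminates every child into its
parent and one forward sweep back-substitutes (Hines ordering) — a single
O(n) exact linear solve per step, unconditionally stable on stiff passive
trees. The solver validity suite pins: RC relaxation within 1 % of the
closed form, sealed-cable steady profiles within 2 % of
cosh((L−x)/λ)/cosh(L/λ), dt-halving (0.05 → 0.025 ms) below 0.05 mV, and
bit-identical repetition under fixed seeds. Voltage clamp is ideal (zero
series resistance) at the soma; the clamp current is the somatic membrane
current plus the axial current leaving the soma plus the capacitive command
current. Resting states are also computed directly by damped Picard
iteration on the equivalent resistive network — identical to an infinite
settle of the integrator to below 1e-4 mV — which the calibration uses for
its inner loops; all reported intrinsic properties come from the −50 pA,
500 ms step protocol.

The ramp command defaults to −150 → −50 mV over 3 s; a −130 mV start is
available by argument, since the two values in circulation differ.

## Calibration

Stage 1 (baseline): with the Kir share s of the resting K⁺ conductance and
the rectification midpoint fixed, a two-dimensional root find on the total
K⁺ density and the Na⁺ density drives (Vm, Rin) to (−71 mV, 92.9 MΩ)
essentially exactly (residuals ≪ the measurement SEMs of 1.3 mV and
11.5 MΩ).

Stage 2 (modulated state): the reduction fraction f, the Kir share s and
the Kir midpoint v_half are fit by least squares (residuals normalized by
the printed SEMs) to the serotonin effect (ΔVm = +6.1 mV,
ΔRin = +31.1 %), re-running stage 1 for every candidate (s, v_half) so the
baseline is always matched. Two ohmic leaks provably cannot satisfy both
targets (closed form in `two_leak_closed_form`: matching ΔRin fixes
f = 0.31 and implies ΔVm = +11.2 mV). With rectification the fit converges
to s ≈ 0.39, v_half ≈ −70 mV, f* ≈ 0.10, matching both targets to the
optimizer tolerance. Two effects of a rectifier with its midpoint near rest
produce the "extra" resistance increase per millivolt of depolarization:
the depolarization itself shuts part of the remaining Kir, and the
hyperpolarizing test step recruits Kir more strongly in the baseline state
than in the reduced one. f* ≈ 0.10 on this two-component pool is not
comparable to the much larger percentage reductions a model with a full
active-channel complement requires, because most of that complement does
not conduct at rest.

Stage 3 (synapse): the synaptic weight and conductance decay are root-found
so a single input 96 µm out produces a 2 mV somatic EPSP (mid-range of the
0.5–5 mV experimental events) decaying with τ = 15 ms. The fitted
conductance decay is ~5–6 ms; the slow somatic decay is largely created by
the membrane, in particular by Kir relaxing as the EPSP decays. The
calibrated reduction prolongs the somatic decay to ~17.5 ms — close to the
experimentally measured shifts (14.7 → 18.6 ms uncaging,
10.4 → 17.4 ms synaptic) though smaller than the 23 ms template value,
which this small-surface-area stand-in cannot reach at matched ΔRin.

## Protocols and measurement conventions

* **Fifth-EPSP amplitude**: maximum of the compound trace within 30 ms
  after the last onset, minus the pre-train baseline (mean over the 50 ms
  before the first onset). Baseline-referenced rather than
  trough-referenced: it matches the template model's "maximum of the
  convolved trace" and remains well defined at every ISI.
* **Compound integral**: ∫(V − baseline) from the first onset to 200 ms
  after the last.
* **Activation order**: most distal synapse first, as in the uncaging
  protocol.
* **Local (iontophoresis-like) modulation**: the K⁺ pool is scaled by
  1 − f·w(d) with a Gaussian w of σ = `extent` (10–15 µm) centred at the
  scan position; only locality is constrained by the experiment, not the
  conductance footprint. Somatic depolarizations of ~1.1–1.6 mV arise for
  proximal placement and decay monotonically with distance, bracketing the
  ~1.2 mV inferred in the experiments.
* **Noisy protocols**: background noise is attached at the midpoint of each
  non-stimulated dendrite and its overall scale is root-found so the
  replicate-averaged Rin (measured with noise active) hits the requested
  value. Summation under noise uses paired noise subtraction: each
  replicate is simulated with and without the synaptic train at the same
  noise seed and the traces subtracted, so the compound EPSP is exactly the
  response of the noisy, shunted membrane with the additive fluctuation
  removed; difference traces are averaged over the 10 replicates
  (seeds 0–9 by default) per condition before metrics, and both conditions
  share the seed list.

## What the analyses show — and their limits

The template model peaks at 14–16 ms ISI (ratio ≈ 1.27) for rise times
1–3 ms: slowing the decay from 15 to 23 ms preferentially helps inputs
arriving 10–20 ms apart. The calibrated compartmental model reproduces the
same tuning from the conductance side: the reduced/baseline amplitude-ratio
curve over ISIs {0.12, 5, 10, 20, 50} ms is
{1.03, 1.10, 1.16, 1.15, 1.09}, peaked at 10 ms.

Under background noise the peak *position* persists at 10 ms at every
tested load (Rin −10 %, −20 %, −33 %), but the enhancement *magnitude*
compresses hard: the ratio curves flatten from peak ≈ 1.04 (−10 %) to
≈ 0.99 (−33 %), where the margin over neighbouring ISIs is below 0.01.
This is a real property of the stand-in, not measurement noise (the paired
estimator reproduces to ~0.002): the Kir-mediated decay prolongation is a
conductance-feedback effect whose gain scales as 1/G_total, so a shunt
adding ~50 % to the total conductance removes most of the τ difference
between the states (noisy-state single-EPSP taus: 9.9 vs 10.1 ms).
A model whose resting conductance is a larger absolute pool — e.g. a full
morphology with several active K⁺ conductances — retains more of its τ
shift under the same relative shunt, so robustness conclusions from this
reduced model are conservative.

Sub-compartment sweeps (f ≤ 0.2, the physiologically relevant range around
f* ≈ 0.10; far larger reductions depolarize the cell beyond its operating
range and the secant Rin is no longer monotone): Vm, Rin and the somatic
EPSP τ all rise monotonically with f; the τ prolongation is dendritic
(soma-only reduction yields ~15–19 % of the dendritic effect, consistent
with the soma's 13 % share of membrane area); somatic EPSP amplitudes are
nearly unchanged (distal synapses boosted slightly more than proximal ones)
while local dendritic amplitudes fall a few percent — transfer improves as
local driving force drops.

The full-model subtracted ramp current reverses at −112.7 mV rather than at
e_K = −107 mV: the unclamped dendrites rest at condition-dependent
potentials, so their axial currents are not common mode — a space-clamp
artifact with the same flavor as the small experimental offset between the
measured (−99 mV) and Nernst-predicted (−101 mV) reversal. An isopotential
control recovers e_K exactly.

## Synthetic data

Generators are pure functions of (parameters, seed) and return their ground
truth: double-exponential EPSP traces (additive Gaussian noise), RC step
responses, stereotyped-spike trains on known DC levels, leak + Kir ramp
current pairs, IPSC event trains with inter-event intervals drawn
uniformly-in-frequency from weighted bands (theta 4–8, alpha 8–12, beta
13–29, low gamma 39–59, high gamma 61–100 Hz; the inter-band gaps are real
and honored — intervals falling in them are reported as unassigned), and
exponentially decaying distance–response curves (multiplicative log-normal
noise). They emulate waveform shape, noise magnitude and event statistics,
not electrode artifacts, drift, or the correlated noise of real recordings
— so the round-trip suite certifies the estimators, not the hardware
robustness of the original measurements.

Estimator conventions worth knowing: decay-τ fits use the 95 %→5 % span of
the decay (starting after the first 5 % excludes the rise-contaminated
shoulder; R² is returned so poor fits can be rejected); reversal estimation
interpolates linearly between bracketing samples and treats crossings
within 3 mV as noise jitter around a single reversal (their mean is
returned); spike filtering excises ±2 ms around each detected peak
(threshold −10 mV), interpolates, and median-filters over 5 ms; Nernst
calculations default to 306.15 K (33 °C).

## Known limitations

* Subthreshold only: no spike-generating conductances, so spike-based
  analyses run on synthetic or experimental traces, not on model output.
* The stand-in's membrane area (~5400 µm²) is several-fold smaller than a
  real FSI's; its membrane time constant (~5 ms at the calibrated
  densities) is correspondingly short, which caps the attainable τ shift
  and makes the noise-robustness result fragile (above).
* The rectifier is phenomenological (instantaneous Boltzmann); Mg²⁺/
  polyamine block biophysics and Kir kinetics are out of scope.
* Ideal somatic voltage clamp; series-resistance artifacts are not
  modelled.
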