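# fsikir

Serotonin depolarizes cortical fast-spiking interneurons (FSIs), raises
their input resistance, and slows the decay of their EPSPs — and by doing
so it selectively boosts the temporal summation of inputs arriving 10–20 ms
apart, i.e. in the gamma band (50–100 Hz). The underlying mechanism is the
suppression of an inward-rectifier K⁺ (Kir) conductance. `fsikir` is an
analysis project that reproduces the computational side of that story:

* a **reduced compartmental FSI model** (soma + five 200 µm × 1.5 µm
  dendrites, Ra = 172 Ω·cm) with split K⁺/Na⁺ ohmic leaks
  (e_K = −107 mV, e_Na = +53 mV), a Boltzmann inward-rectifier K⁺
  conductance, double-exponential synapses (e_syn = 0 mV) and
  Ornstein–Uhlenbeck point-conductance background noise, integrated with a
  semi-implicit (backward-Euler, Hines-ordered) cable solver written here
  and accelerated with numba;
* the **algebraic EPSP-convolution model**: unit-peak double-exponential
  templates `v(t) = (1/normfac)·(e^{−t/τ_slow} − e^{−t/τ_fast})` with
  τ_slow = 15 ms (baseline) vs 23 ms (serotonin) convolved with five
  impulses at varying inter-stimulus intervals (ISI);
* the **trace-analysis toolkit** used on the recordings: exponential
  decay-τ fits, Ohm's-law input resistance, voltage-ramp I–V subtraction
  (reversal, slope-conductance change, charge transfer), compound-EPSP
  summation metrics, spike detection / PSTHs / spike-filtered subthreshold
  voltage, inter-event-interval frequency-band probabilities, space-constant
  fits and the Nernst potential;
* **synthetic-data generators** that produce all of the above inputs with
  known ground truth (the study deposited no raw data), so every estimator
  is validated by parameter recovery.

## Worked example

```sh
python analysis/02_calibrate_model.py
```

prints (abridged):

```
Two-leak counterexample: matching +31.1% Rin forces dVm = 11.20 mV
(measured 6.1 ± 1.1) -> not jointly matchable.
Baseline: Vm = -71.00 mV, Rin = 92.90 MOhm
Modulated state: f* = 0.102 of the Kir+K-leak pool, Kir share 0.39, v_half -70.0 mV
  dVm = +6.10 mV, dRin = +31.10 %  (converged: True)
Single dendritic EPSP (96 um): 2.00 mV, tau 15.0 ms -> 2.17 mV, tau 17.5 ms
after reduction (amplitude change +8.3 %)
```

The first line is the key structural result: two purely ohmic leaks cannot
reproduce the measured effect pair — matching the +31.1 % input-resistance
increase forces an ~11 mV depolarization, nearly twice the measured
+6.1 ± 1.1 mV. A K⁺ pool that rectifies (shuts with depolarization) matches
both exactly; the fit puts ~39 % of the resting K⁺ conductance in the
rectifier with half-inactivation near the resting potential, and the
serotonin state corresponds to removing ~10 % of that pool. The calibrated
reduction then prolongs the somatic EPSP decay (15 → 17.5 ms) while leaving
its amplitude nearly unchanged — exactly the synaptic phenotype observed.

Running `python analysis/04_summation_vs_isi.py` afterwards stimulates the
five dendritic synapses (96–100 µm from the soma, most distal first) at
ISIs 0.12–50 ms in both states and prints the fifth-EPSP amplitude ratios
(reduced/baseline): `1.03, 1.10, 1.16, 1.15, 1.09` — peaked at 10 ms,
i.e. the enhancement is gamma-band selective. The remaining scripts cover
the template model (`01`), sub-compartment reduction sweeps (`03`),
background-noise robustness (`05`), ramp I–V subtraction (`06`),
estimator round-trips (`07`) and the iontophoresis-like local modulation
scan (`08`); each writes its tables to `results/`.

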