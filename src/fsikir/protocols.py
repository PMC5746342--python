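"""In-silico experimental protocols driven over a :class:`CellModel`.

These reproduce the study's simulation experiments: K⁺-reduction sweeps over
cellular sub-compartments, single-EPSP responses, ISI summation series at
baseline versus the reduced-g_K state, background-noise replicates with
Rin-matched scaling, and spatially restricted (iontophoresis-like)
conductance modulation scans.
"""
from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .calibrate import _steady_vm_rin
from .engine import measure_resting_state, run_current_clamp, solve_steady_state
from .ephys import TauFit, fit_decay_tau, summation_metrics
from .mechanisms import NoiseSpec
from .model import SYNAPSE_DISTANCES, CellModel
from .records import TraceRecord

__all__ = [
    "EpspResponse",
    "GkSweepResult",
    "SummationResult",
    "epsp_response",
    "run_gk_sweep",
    "run_summation",
    "summation_comparison",
    "run_noise_replicates",
    "scale_noise_to_rin",
    "run_local_modulation_scan",
]

#: Settle time before any stimulus, ms (runs start from the exact steady
#: state, so this only absorbs discretization transients and noise warm-up).
SETTLE_MS = 150.0
#: Post-train recording window, ms.
TAIL_MS = 250.0


@dataclass(frozen=True)
class EpspResponse:
    somatic_amplitude: float  # mV
    somatic_tau: TauFit
    local_amplitude: float  # mV at the synapse compartment
    trace: TraceRecord


@dataclass(frozen=True)
class GkSweepResult:
    """Per-reduction-fraction intrinsic and single-EPSP measurements."""

    fractions: np.ndarray
    scope: str
    vm: np.ndarray  # mV
    rin: np.ndarray  # MΩ
    epsp_amplitude: np.ndarray  # mV, somatic
    epsp_tau: np.ndarray  # ms, somatic decay
    local_amplitude: np.ndarray  # mV, at the synapse


@dataclass(frozen=True)
class SummationResult:
    """Per-ISI compound-EPSP metrics for two conditions and their ratios."""

    isis: np.ndarray  # ms
    amplitude_baseline: np.ndarray  # last-EPSP amplitude, mV
    amplitude_reduced: np.ndarray
    integral_baseline: np.ndarray  # mV·ms
    integral_reduced: np.ndarray
    n_inputs: int

    @property
    def amplitude_ratio(self) -> np.ndarray:
        return self.amplitude_reduced / self.amplitude_baseline

    @property
    def integral_ratio(self) -> np.ndarray:
        return self.integral_reduced / self.integral_baseline

    def argmax_isi(self, metric: str = "amplitude") -> float:
        r = self.amplitude_ratio if metric == "amplitude" else self.integral_ratio
        return float(self.isis[int(np.argmax(r))])


def _settled_run(model: CellModel, duration: float, record,
                 noise_seed: int | None = None) -> dict[int, TraceRecord]:
    v0 = solve_steady_state(model.tree, model.mech, model.config)
    return run_current_clamp(model.tree, model.mech, duration, (),
                             model.config, record=tuple(record), v_init=v0,
                             noise_seed=noise_seed)


def epsp_response(
    model: CellModel,
    site_distance: float = 96.0,
    dendrite_section: int = 1,
    tau_rise: float = 0.5,
    tau_decay: float = 14.0,
    weight: float = 1e-3,
    noise_seed: int | None = None,
) -> EpspResponse:
    """Somatic and local response to a single synapse at ``site_distance``.

    The model settles from its exact steady state, one synaptic event fires
    at ``SETTLE_MS``, and the somatic EPSP amplitude (peak − pre-onset
    baseline) and decay tau are measured.
    """
    m = model.with_synapses(distances=(site_distance,),
                            dendrite_section=dendrite_section,
                            tau_rise=tau_rise, tau_decay=tau_decay,
                            weight=weight,
                            onsets_per_synapse=[(SETTLE_MS,)])
    syn_comp = m.mech.synapses[0].compartment
    duration = SETTLE_MS + TAIL_MS
    traces = _settled_run(m, duration, (0, syn_comp), noise_seed=noise_seed)
    soma = traces[0]
    local = traces[syn_comp]
    base = float(np.mean(soma.window(SETTLE_MS - 50.0, SETTLE_MS)))
    amp = float(np.max(soma.window(SETTLE_MS, duration))) - base
    base_l = float(np.mean(local.window(SETTLE_MS - 50.0, SETTLE_MS)))
    amp_l = float(np.max(local.window(SETTLE_MS, duration))) - base_l
    tau = fit_decay_tau(soma, peak_window=(SETTLE_MS, duration), baseline=base)
    return EpspResponse(somatic_amplitude=amp, somatic_tau=tau,
                        local_amplitude=amp_l, trace=soma)


def run_gk_sweep(
    model: CellModel,
    fractions,
    scope: str = "both",
    site_distance: float = 96.0,
    dendrite_section: int = 1,
    tau_rise: float = 0.5,
    tau_decay: float = 14.0,
    weight: float = 1e-3,
) -> GkSweepResult:
    """Scale the K⁺ pool by (1−f) in the scoped compartments for each f,
    re-measuring rest (−50 pA Ohm's law) and the single-EPSP response."""
    fractions = np.asarray(sorted(fractions), dtype=float)
    if np.any(fractions < 0) or np.any(fractions > 0.95):
        raise ValueError("fractions must lie in [0, 0.95]")
    vm = np.empty_like(fractions)
    rin = np.empty_like(fractions)
    amp = np.empty_like(fractions)
    tau = np.empty_like(fractions)
    loc = np.empty_like(fractions)
    for k, f in enumerate(fractions):
        m = model.with_reduction(float(f), scope=scope) if f > 0 else model
        vm[k], rin[k] = measure_resting_state(m.tree, m.mech, m.config)
        r = epsp_response(m, site_distance, dendrite_section,
                          tau_rise, tau_decay, weight)
        amp[k], tau[k], loc[k] = (r.somatic_amplitude, r.somatic_tau.tau,
                                  r.local_amplitude)
    return GkSweepResult(fractions=fractions, scope=scope, vm=vm, rin=rin,
                         epsp_amplitude=amp, epsp_tau=tau, local_amplitude=loc)


def run_summation(
    model: CellModel,
    isi: float,
    n_inputs: int = 5,
    sites=SYNAPSE_DISTANCES,
    tau_rise: float = 0.5,
    tau_decay: float = 14.0,
    weight: float = 1e-3,
    noise_seed: int | None = None,
) -> tuple[float, float]:
    """Compound-EPSP metrics for one ISI on one model.

    The ``n_inputs`` synapses fire once each, most distal first (``sites``
    must be ordered distal → proximal), separated by ``isi`` ms.  Returns
    (last-EPSP amplitude mV, compound integral mV·ms) per
    :func:`fsikir.ephys.summation_metrics`.
    """
    sites = tuple(sites)[:n_inputs]
    if len(sites) != n_inputs:
        raise ValueError("need one site per input")
    onsets = [(SETTLE_MS + k * isi,) for k in range(n_inputs)]
    m = model.with_synapses(distances=sites, tau_rise=tau_rise,
                            tau_decay=tau_decay, weight=weight,
                            onsets_per_synapse=onsets)
    duration = SETTLE_MS + (n_inputs - 1) * isi + TAIL_MS
    soma = _settled_run(m, duration, (0,), noise_seed=noise_seed)[0]
    flat = [o[0] for o in onsets]
    return summation_metrics(soma, flat)


def summation_comparison(
    baseline: CellModel,
    reduced: CellModel,
    isis,
    n_inputs: int = 5,
    sites=SYNAPSE_DISTANCES,
    tau_rise: float = 0.5,
    tau_decay: float = 14.0,
    weight: float = 1e-3,
    noise_seed: int | None = None,
) -> SummationResult:
    """ISI summation series at baseline versus the reduced-g_K state.

    Both conditions share synapse placement, parameters and (when noisy)
    the noise seed, so ratios isolate the effect of the K⁺ reduction.
    """
    isis = np.asarray(isis, dtype=float)
    ab, ar, ib, ir = (np.empty_like(isis) for _ in range(4))
    for k, isi in enumerate(isis):
        ab[k], ib[k] = run_summation(baseline, float(isi), n_inputs, sites,
                                     tau_rise, tau_decay, weight, noise_seed)
        ar[k], ir[k] = run_summation(reduced, float(isi), n_inputs, sites,
                                     tau_rise, tau_decay, weight, noise_seed)
    return SummationResult(isis=isis, amplitude_baseline=ab,
                           amplitude_reduced=ar, integral_baseline=ib,
                           integral_reduced=ir, n_inputs=n_inputs)


def run_noise_replicates(
    model: CellModel,
    noise: NoiseSpec,
    n_replicates: int = 10,
    base_seed: int = 0,
    protocol=None,
):
    """Run a protocol under independent background-noise seeds.

    ``protocol(model, seed)`` is called once per replicate on the model with
    noise attached; returns (list of protocol outputs, per-replicate Rin
    measured with the noise active).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    outputs, rins = [], []
    for r in range(n_replicates):
        seed = base_seed + r
        m = model.with_noise(dc_replace(noise, seed=seed))
        _, rin = measure_resting_state(m.tree, m.mech, m.config,
                                       noise_seed=seed)
        rins.append(rin)
        if protocol is not None:
            outputs.append(protocol(m, seed))
    return outputs, np.asarray(rins)


def scale_noise_to_rin(
    model: CellModel,
    noise: NoiseSpec,
    target_rin: float,
    n_replicates: int = 3,
    base_seed: int = 0,
    scale_bracket: tuple[float, float] = (0.05, 40.0),
) -> tuple[float, float]:
    """Find the noise scale at which the replicate-mean Rin hits ``target_rin``.

    Mean Rin is strictly decreasing in the scale (added shunt), so a scalar
    root find on log-scale suffices.  Returns (scale, achieved mean Rin).
    """
    from scipy.optimize import brentq

    def mean_rin(log_scale: float) -> float:
        sc = float(np.exp(log_scale))
        _, rins = run_noise_replicates(
            model.with_noise(None), dc_replace(noise, scale=sc),
            n_replicates=n_replicates, base_seed=base_seed)
        return float(np.mean(rins))

    lo, hi = np.log(scale_bracket[0]), np.log(scale_bracket[1])
    root = brentq(lambda x: mean_rin(x) - target_rin, lo, hi, xtol=1e-3)
    scale = float(np.exp(root))
    achieved = mean_rin(root)
    return scale, achieved


def run_noise_summation(
    baseline: CellModel,
    reduced: CellModel,
    noise: NoiseSpec,
    isis,
    n_replicates: int = 10,
    base_seed: int = 0,
    sites=SYNAPSE_DISTANCES,
    tau_rise: float = 0.5,
    tau_decay: float = 14.0,
    weight: float = 1e-3,
) -> SummationResult:
    """ISI summation series under background noise, replicate-averaged.

    For each replicate seed the noisy cell is simulated twice — with the
    synaptic train and with silent synapses, at the identical noise
    realization — and the traces are subtracted.  The difference trace is
    the compound EPSP as integrated by the noisy, shunted membrane (the
    noise's conductance load acts on the synaptic response; only the
    additive fluctuation is removed).  Difference traces are averaged over
    the ``n_replicates`` seeds per condition before the summation metrics
    are taken, mirroring how repeated experimental sweeps are averaged.
    Both conditions share the seed list.
    """
    isis = np.asarray(isis, dtype=float)
    seeds = [base_seed + r for r in range(n_replicates)]
    n_inputs = len(tuple(sites))

    def mean_difference(model: CellModel, isi: float):
        onsets = [(SETTLE_MS + k * isi,) for k in range(n_inputs)]
        m_on = model.with_synapses(distances=sites, tau_rise=tau_rise,
                                   tau_decay=tau_decay, weight=weight,
                                   onsets_per_synapse=onsets)
        m_off = model.without_synapses()
        duration = SETTLE_MS + (n_inputs - 1) * isi + TAIL_MS
        acc = None
        dt = None
        for s in seeds:
            on = _settled_run(m_on.with_noise(
                dc_replace(noise, seed=s)), duration, (0,), noise_seed=s)[0]
            off = _settled_run(m_off.with_noise(
                dc_replace(noise, seed=s)), duration, (0,), noise_seed=s)[0]
            diff = on.samples - off.samples
            acc = diff if acc is None else acc + diff
            dt = on.dt
        trace = TraceRecord(dt=dt, samples=acc / len(seeds))
        return summation_metrics(trace, [o[0] for o in onsets])

    ab, ar, ib, ir = (np.empty_like(isis) for _ in range(4))
    for k, isi in enumerate(isis):
        ab[k], ib[k] = mean_difference(baseline, float(isi))
        ar[k], ir[k] = mean_difference(reduced, float(isi))
    return SummationResult(isis=isis, amplitude_baseline=ab,
                           amplitude_reduced=ar, integral_baseline=ib,
                           integral_reduced=ir, n_inputs=n_inputs)


def run_local_modulation_scan(
    model: CellModel,
    center_distances,
    extent: float,
    f: float,
    dendrite_section: int = 1,
) -> np.ndarray:
    """Iontophoresis-like scan: Gaussian-weighted local K⁺ reduction.

    For each scan center d₀ (µm path distance), K⁺ densities on the target
    dendrite are scaled by 1 − f·w(d) with w(d) = exp(−(d−d₀)²/(2·extent²)),
    and the steady somatic depolarization relative to the unmodulated model
    is reported.
    """
    if extent <= 0:
        raise ValueError("extent must be > 0")
    dist = np.array([
        model.tree.path_distance(c.index)
        if c.section_id == dendrite_section else np.nan
        for c in model.tree.compartments
    ])
    on_dend = ~np.isnan(dist)
    v_base = solve_steady_state(model.tree, model.mech, model.config)[0]
    out = np.empty(len(tuple(center_distances)))
    for k, d0 in enumerate(center_distances):
        w = np.zeros(len(model.tree))
        w[on_dend] = f * np.exp(-((dist[on_dend] - d0) ** 2)
                                / (2.0 * extent**2))
        m = model.with_graded_reduction(w)
        out[k] = solve_steady_state(m.tree, m.mech, m.config)[0] - v_base
    return out
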