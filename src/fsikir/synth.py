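"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of its parameters and a seed, returns the
exact generating parameters alongside the data, and is paired with an
estimator in :mod:`fsikir.ephys` that must recover those parameters within
documented tolerances (the round-trip suite in the tests).  Defaults mirror
the magnitudes the analyses are used at: EPSP decay taus around 10–19 ms,
input resistance near 93 MΩ, ramp currents with a Kir component reversing
near −101 mV, IPSC trains with theta-through-gamma band structure, and
firing-rate-versus-distance data with a ~3 µm space constant.

Noise models: additive Gaussian for voltage traces, multiplicative
log-normal for distance responses, none for event times (the inter-event-
interval randomness is itself the signal).
"""
from __future__ import annotations

import numpy as np

from .ephys import BandDefinition
from .mechanisms import KirSpec, kir_open_fraction, synaptic_peak_time
from .records import EventSeries, IVCurve, TraceRecord

__all__ = [
    "gen_epsp_trace",
    "gen_step_trace",
    "gen_spiking_trace",
    "gen_vc_ramp_pair",
    "gen_ipsc_events",
    "gen_distance_response",
]


def _double_exp(t, amplitude, tau_rise, tau_decay):
    tp = synaptic_peak_time(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    tt = np.clip(t, 0, None)
    return amplitude / peak * np.where(
        t >= 0, np.exp(-tt / tau_decay) - np.exp(-tt / tau_rise), 0.0)


def gen_epsp_trace(
    onsets=(100.0,),
    amplitude: float = 2.0,  # mV
    tau_rise: float = 0.5,
    tau_decay: float = 10.4,
    baseline: float = -71.0,
    dt: float = 0.1,
    duration: float = 400.0,
    noise_sd: float = 0.0,  # mV additive Gaussian
    seed: int = 0,
) -> tuple[TraceRecord, dict]:
    """Current-clamp voltage trace with double-exponential EPSPs."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    v = np.full_like(t, baseline)
    for o in onsets:
        v += _double_exp(t - o, amplitude, tau_rise, tau_decay)
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(t.size)
    truth = {"amplitude": amplitude, "tau_rise": tau_rise,
             "tau_decay": tau_decay, "baseline": baseline,
             "onsets": tuple(onsets), "noise_sd": noise_sd, "seed": seed}
    return TraceRecord(dt=dt, samples=v, kind="voltage", site="synthetic",
                       meta=truth), truth


def gen_step_trace(
    rin: float = 92.9,  # MΩ
    tau_m: float = 10.0,  # ms
    step_amplitude: float = -0.05,  # nA
    step_window: tuple[float, float] = (200.0, 700.0),
    baseline: float = -71.0,
    dt: float = 0.1,
    duration: float = 900.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TraceRecord, dict]:
    """RC (single time constant) response to a current step."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    dv = rin * step_amplitude  # mV steady deflection
    t_on, t_off = step_window
    v = np.full_like(t, baseline)
    on = (t >= t_on) & (t < t_off)
    v[on] += dv * (1.0 - np.exp(-(t[on] - t_on) / tau_m))
    off = t >= t_off
    v_off = dv * (1.0 - np.exp(-(t_off - t_on) / tau_m))
    v[off] += v_off * np.exp(-(t[off] - t_off) / tau_m)
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(t.size)
    truth = {"rin": rin, "tau_m": tau_m, "step_amplitude": step_amplitude,
             "step_window": step_window, "baseline": baseline, "seed": seed}
    return TraceRecord(dt=dt, samples=v, kind="voltage", site="synthetic",
                       meta=truth), truth


def gen_spiking_trace(
    rate_hz: float = 20.0,
    duration: float = 2000.0,
    baseline: float = -65.0,
    dc_shift: float = 0.0,  # mV added over the whole trace
    spike_amplitude: float = 75.0,  # mV above baseline
    spike_half_width: float = 0.4,  # ms (Gaussian sigma)
    dt: float = 0.05,
    noise_sd: float = 0.2,
    refractory: float = 5.0,  # ms between spikes
    seed: int = 0,
) -> tuple[TraceRecord, dict]:
    """Voltage trace with stereotyped spikes on a known DC level.

    Spike times are a Poisson process thinned by the refractory period; each
    spike is a Gaussian bump (fast enough to be excised cleanly by the
    spike-filtering analysis).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    level = baseline + dc_shift
    v = np.full_like(t, level)
    times = []
    t_next = rng.exponential(1000.0 / rate_hz)
    while t_next < duration - 5.0:
        if not times or t_next - times[-1] >= refractory:
            times.append(t_next)
        t_next += rng.exponential(1000.0 / rate_hz)
    for ts in times:
        sl = (t > ts - 3.0) & (t < ts + 3.0)
        v[sl] += spike_amplitude * np.exp(-((t[sl] - ts) ** 2)
                                          / (2 * spike_half_width**2))
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(t.size)
    truth = {"rate_hz": rate_hz, "dc_level": level, "dc_shift": dc_shift,
             "spike_times": tuple(times), "seed": seed}
    return TraceRecord(dt=dt, samples=v, kind="voltage", site="synthetic",
                       meta={"dc_level": level}), truth


def gen_vc_ramp_pair(
    g_leak: float = 0.008,  # µS
    e_leak: float = -55.0,
    g_kir: float = 0.006,  # µS maximal
    e_k: float = -101.0,
    v_half: float = -85.0,
    k_slope: float = 12.0,
    kir_reduction: float = 0.7,
    v_start: float = -150.0,
    v_end: float = -50.0,
    n_points: int = 600,
    noise_sd: float = 0.0,  # nA
    seed: int = 0,
) -> tuple[IVCurve, IVCurve, dict]:
    """Ramp I–V pair: linear leak + Boltzmann Kir, before and after scaling
    the Kir conductance by (1 − kir_reduction)."""
    rng = np.random.default_rng(seed)
    v = np.linspace(v_start, v_end, n_points)
    kir = KirSpec(g_density=0.0, e_k=e_k, v_half=v_half, k_slope=k_slope)
    m = kir_open_fraction(v, kir)

    def current(scale):
        i = g_leak * (v - e_leak) + scale * g_kir * m * (v - e_k)
        if noise_sd > 0:
            i = i + noise_sd * rng.standard_normal(v.size)
        return i

    base = IVCurve(v=v, i=current(1.0), condition="baseline",
                   ramp_duration=3000.0)
    reduced = IVCurve(v=v, i=current(1.0 - kir_reduction),
                      condition="reduced", ramp_duration=3000.0)
    truth = {"e_k": e_k, "g_leak": g_leak, "g_kir": g_kir,
             "kir_reduction": kir_reduction, "v_half": v_half,
             "k_slope": k_slope, "seed": seed}
    return base, reduced, truth


def gen_ipsc_events(
    n_events: int = 2000,
    band_weights: dict | None = None,
    bands: BandDefinition = BandDefinition(),
    t0: float = 0.0,
    amplitude_mean: float = 50.0,  # pA
    amplitude_cv: float = 0.3,
    seed: int = 0,
) -> tuple[EventSeries, dict]:
    """Event train whose inter-event intervals are drawn from a weighted
    mixture of uniform-in-frequency band distributions.

    ``band_weights`` maps band names to mixture weights summing to 1; every
    IEI picks a band, then a frequency uniform in that band, then
    IEI = 1000/f ms.
    """
    if band_weights is None:
        band_weights = {"theta": 0.1, "alpha": 0.1, "beta": 0.3,
                        "low_gamma": 0.3, "high_gamma": 0.2}
    names = list(band_weights)
    w = np.array([band_weights[n] for n in names], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("band weights must sum to 1")
    limits = {name: (lo, hi) for name, lo, hi in bands.bands}
    for n in names:
        if n not in limits:
            raise ValueError(f"unknown band {n!r}")
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(names), size=n_events, p=w)
    lows = np.array([limits[n][0] for n in names])
    highs = np.array([limits[n][1] for n in names])
    freqs = rng.uniform(lows[choice], highs[choice])
    ieis = 1000.0 / freqs
    times = t0 + np.cumsum(ieis)
    amps = np.clip(amplitude_mean * (1.0 + amplitude_cv
                                     * rng.standard_normal(n_events)),
                   1e-3, None)
    truth = {"band_weights": dict(band_weights), "n_events": n_events,
             "seed": seed}
    return EventSeries(times=times, amplitudes=amps, meta=truth), truth


def gen_distance_response(
    distances=None,
    amplitude: float = 12.0,  # response at distance 0 (e.g. Δfiring rate, Hz)
    space_constant: float = 3.13,  # µm
    noise_cv: float = 0.0,  # multiplicative log-normal sigma
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Response versus distance decaying as A·exp(−d/λ)."""
    if space_constant <= 0:
        raise ValueError("space constant must be > 0")
    if distances is None:
        distances = np.linspace(0.0, 10.0, 16)
    d = np.asarray(distances, dtype=float)
    rng = np.random.default_rng(seed)
    y = amplitude * np.exp(-d / space_constant)
    if noise_cv > 0:
        y = y * np.exp(noise_cv * rng.standard_normal(d.size)
                       - 0.5 * noise_cv**2)
    truth = {"amplitude": amplitude, "space_constant": space_constant,
             "noise_cv": noise_cv, "seed": seed}
    return d, y, truth
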