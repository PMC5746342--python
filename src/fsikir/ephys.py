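"""Measurement procedures applied to traces, I–V curves and event trains.

These are the analysis operations of the study: exponential decay-tau fits,
Ohm's-law input resistance, ramp I–V subtraction with reversal / slope /
charge-transfer quantification, compound-EPSP summation metrics, spike
detection and PSTHs, spike-filtered subthreshold voltage, inter-event-
interval frequency-band probabilities, space-constant fits, and the Nernst
potential.  Every estimator is paired with a generator in
:mod:`fsikir.synth` that produces traces with known ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np
from scipy import optimize, signal, stats

from .records import EventSeries, IVCurve, TraceRecord

__all__ = [
    "AnalysisError",
    "FitError",
    "BandDefinition",
    "TauFit",
    "SpaceConstantFit",
    "fit_decay_tau",
    "input_resistance_from_step",
    "iv_difference",
    "estimate_reversal",
    "slope_conductance_change",
    "charge_transfer",
    "summation_metrics",
    "detect_spikes",
    "firing_rate_psth",
    "spike_fraction_by_isi",
    "subthreshold_from_spiking",
    "iei_band_probabilities",
    "fit_space_constant",
    "nernst_potential",
]

GAS_CONSTANT = 8.31446261815324  # J/(mol·K)
FARADAY = 96485.33212  # C/mol


class AnalysisError(ValueError):
    pass


class FitError(AnalysisError):
    pass


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency bands, Hz.  Gaps between bands are honored literally;
    at a shared edge the lower band wins (8 Hz is theta, not alpha)."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 13.0, 29.0),
        ("low_gamma", 39.0, 59.0),
        ("high_gamma", 61.0, 100.0),
    )

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise AnalysisError(f"band {name}: need low < high")

    def assign(self, freq_hz: float) -> str | None:
        for name, lo, hi in sorted(self.bands, key=lambda b: b[1]):
            if lo <= freq_hz <= hi:
                return name
        return None

    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)


@dataclass(frozen=True)
class TauFit:
    tau: float  # ms
    r_squared: float
    amplitude: float
    baseline: float


@dataclass(frozen=True)
class SpaceConstantFit:
    space_constant: float  # µm (inf if non-decaying)
    amplitude: float
    r_squared: float
    decaying: bool


def fit_decay_tau(
    trace: TraceRecord,
    peak_window: tuple[float, float] | None = None,
    baseline: float | None = None,
) -> TauFit:
    """Single-exponential fit to the decay of an EPSP-like transient.

    The peak is located inside ``peak_window`` (whole trace by default); the
    fit runs from the sample after the peak to the point of 95 % decay back
    toward baseline (or the trace end).  ``baseline`` defaults to the first
    sample.  The fit is invariant to amplitude scaling and baseline offset.
    """
    v = trace.samples
    t = trace.time
    if baseline is None:
        baseline = float(v[0])
    if peak_window is None:
        i0, i1 = 0, v.size - 1
    else:
        i0, i1 = trace.index_at(peak_window[0]), trace.index_at(peak_window[1])
    if i1 <= i0:
        raise AnalysisError("empty peak window")
    ipk = i0 + int(np.argmax(v[i0:i1 + 1]))
    amp = v[ipk] - baseline
    if amp <= 0:
        raise FitError("no positive transient above baseline")
    rel = v[ipk:] - baseline
    # fit the 95 %→5 % portion of the decay: starting after the first 5 %
    # of decay excludes the flat top still shaped by the rise exponential
    below_start = np.nonzero(rel <= 0.95 * amp)[0]
    istart = ipk + (int(below_start[0]) if below_start.size else 1)
    below = np.nonzero(rel <= 0.05 * amp)[0]
    iend = ipk + int(below[0]) if below.size else v.size - 1
    sl = slice(max(istart, ipk + 1), max(iend, ipk + 5) + 1)
    tt = t[sl] - t[ipk]
    vv = v[sl]
    if vv.size < 4 or vv[-1] >= vv[0]:
        raise FitError("segment after the peak does not decay")

    def model(x, a, tau, c):
        return c + a * np.exp(-x / tau)

    guess_tau = max((tt[-1] - tt[0]) / 3.0, trace.dt)
    try:
        popt, _ = optimize.curve_fit(
            model, tt, vv, p0=(amp, guess_tau, baseline),
            bounds=([0, trace.dt * 0.1, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"decay fit failed: {exc}") from None
    resid = vv - model(tt, *popt)
    ss_tot = float(np.sum((vv - vv.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return TauFit(tau=float(popt[1]), r_squared=r2,
                  amplitude=float(popt[0]), baseline=float(popt[2]))


def input_resistance_from_step(
    trace: TraceRecord,
    step_amplitude: float,
    step_window: tuple[float, float],
) -> float:
    """Ohm's-law input resistance (MΩ) from a current-step voltage trace.

    Baseline is the mean voltage over the 100 ms (or whatever is available)
    before the step; the steady level is the mean over the final 20 % of the
    step.  Warns if the step is shorter than ~5 fitted membrane time
    constants.
    """
    if step_amplitude == 0:
        raise AnalysisError("step amplitude must be nonzero")
    t_on, t_off = step_window
    # boundary samples excluded: the sample at t_on is already stepped and
    # the one at t_off already released
    pre = trace.window(max(trace.t0, t_on - 100.0), t_on - trace.dt)
    v0 = float(np.mean(pre))
    steady = trace.window(t_off - 0.2 * (t_off - t_on), t_off - trace.dt)
    dv = float(np.mean(steady)) - v0
    # crude τm estimate from 63 % crossing, for the length check only
    seg = trace.window(t_on, t_off)
    if dv != 0:
        frac = (seg - v0) / dv
        idx = np.nonzero(frac >= 0.632)[0]
        if idx.size:
            tau_est = idx[0] * trace.dt
            if (t_off - t_on) < 5 * tau_est:
                warnings.warn("step window shorter than 5 membrane time "
                              "constants; Rin may be underestimated")
    return dv / step_amplitude


def iv_difference(minuend: IVCurve, subtrahend: IVCurve) -> IVCurve:
    """Pointwise current difference (minuend − subtrahend) on the minuend's
    voltage grid; the subtrahend is interpolated if its grid differs."""
    if np.array_equal(minuend.v, subtrahend.v):
        i_sub = subtrahend.i
    else:
        lo = max(minuend.v[0], subtrahend.v[0])
        hi = min(minuend.v[-1], subtrahend.v[-1])
        if hi <= lo:
            raise AnalysisError("voltage grids do not overlap")
        keep = (minuend.v >= lo) & (minuend.v <= hi)
        v = minuend.v[keep]
        i_sub = np.interp(v, subtrahend.v, subtrahend.i)
        return IVCurve(v=v, i=minuend.i[keep] - i_sub,
                       condition=f"{minuend.condition}-{subtrahend.condition}",
                       ramp_duration=minuend.ramp_duration)
    return IVCurve(v=minuend.v, i=minuend.i - i_sub,
                   condition=f"{minuend.condition}-{subtrahend.condition}",
                   ramp_duration=minuend.ramp_duration)


def estimate_reversal(curve: IVCurve, cluster_window: float = 3.0) -> float:
    """Reversal potential (mV): the unique interior zero crossing of the
    I–V curve, located by linear interpolation between bracketing samples.

    Noise jitter produces several crossings within a narrow voltage window;
    crossings closer than ``cluster_window`` mV are treated as one (their
    mean is returned).  Genuinely separate crossings raise an error.
    """
    i = curve.i
    v = curve.v
    sign = np.sign(i)
    crossings = []
    for k in range(i.size - 1):
        if sign[k] == 0:
            if 0 < k:
                crossings.append(v[k])
        elif sign[k] * sign[k + 1] < 0:
            frac = i[k] / (i[k] - i[k + 1])
            crossings.append(v[k] + frac * (v[k + 1] - v[k]))
    if sign[-1] == 0:
        crossings.append(v[-1])
    if not crossings:
        raise AnalysisError("I-V curve does not cross zero")
    clusters = [[crossings[0]]]
    for c in crossings[1:]:
        if c - clusters[-1][-1] > cluster_window:
            clusters.append([c])
        else:
            clusters[-1].append(c)
    if len(clusters) > 1:
        raise AnalysisError(
            f"multiple zero crossings near {[c[0] for c in clusters]}")
    return float(np.mean(clusters[0]))


def slope_conductance_change(
    base: IVCurve, post: IVCurve, fit_range: tuple[float, float]
) -> float:
    """Change (post − base) in the OLS slope of the I–V curves over
    ``fit_range`` — i.e. the conductance change, µS."""
    out = []
    for curve in (base, post):
        keep = (curve.v >= fit_range[0]) & (curve.v <= fit_range[1])
        if keep.sum() < 5:
            raise AnalysisError("fewer than 5 samples in the fit range")
        res = stats.linregress(curve.v[keep], curve.i[keep])
        out.append(res.slope)
    return float(out[1] - out[0])


def charge_transfer(obj: IVCurve | TraceRecord) -> float:
    """Trapezoidal charge (nC) of a current signal over time.

    For an :class:`IVCurve` from a ramp the time axis is reconstructed from
    the stored ramp duration (the command is linear in time).
    """
    if isinstance(obj, TraceRecord):
        if obj.kind != "current":
            raise AnalysisError("need a current trace")
        t = obj.time
        i = obj.samples
    else:
        if obj.ramp_duration is None:
            raise AnalysisError("IVCurve lacks ramp duration; no time axis")
        t = np.linspace(0.0, obj.ramp_duration, obj.v.size)
        i = obj.i
    return float(np.trapezoid(i, t) / 1e3)  # nA·ms → nC


def summation_metrics(
    compound: TraceRecord,
    onsets,
    amplitude_window: float = 30.0,
    integral_window: float = 200.0,
    baseline_window: float = 50.0,
) -> tuple[float, float]:
    """Last-EPSP amplitude (mV) and compound integral (mV·ms).

    Amplitude: maximum of the compound trace within ``amplitude_window`` ms
    after the last onset, minus the pre-train baseline (mean over
    ``baseline_window`` ms before the first onset).  Integral: ∫(V − baseline)
    over [first onset, last onset + ``integral_window``].
    """
    onsets = sorted(onsets)
    t_first, t_last = onsets[0], onsets[-1]
    if t_first < compound.t0 or t_last > compound.t0 + compound.duration:
        raise AnalysisError("onsets outside the trace")
    base = compound.window(max(compound.t0, t_first - baseline_window), t_first)
    baseline = float(np.mean(base))
    if float(np.max(base) - np.min(base)) > 1.0:
        warnings.warn("baseline window looks contaminated by events")
    seg = compound.window(t_last, t_last + amplitude_window)
    amplitude = float(np.max(seg)) - baseline
    integ_seg = compound.window(t_first, t_last + integral_window)
    integral = float(np.trapezoid(integ_seg - baseline, dx=compound.dt))
    return amplitude, integral


def detect_spikes(
    trace: TraceRecord,
    threshold: float = -10.0,
    refractory: float = 1.0,
) -> EventSeries:
    """Threshold-crossing spike detection.

    Upward crossings of ``threshold`` separated by at least ``refractory``
    ms; each event is stamped at the local voltage maximum of its
    suprathreshold excursion.
    """
    v = trace.samples
    above = v >= threshold
    up = np.nonzero(~above[:-1] & above[1:])[0] + 1
    times, amps = [], []
    last_t = -np.inf
    for k in up:
        end = k
        while end < v.size and above[end]:
            end += 1
        ipk = k + int(np.argmax(v[k:end]))
        tpk = trace.t0 + ipk * trace.dt
        if tpk - last_t < refractory:
            continue
        times.append(tpk)
        amps.append(float(v[ipk]))
        last_t = tpk
    return EventSeries(times=np.array(times), amplitudes=np.array(amps),
                       meta={"threshold": threshold, "method": "crossing"})


def firing_rate_psth(
    events: EventSeries,
    bin_ms: float,
    window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram: (bin centers ms, firing rate Hz)."""
    if bin_ms <= 0:
        raise AnalysisError("bin width must be > 0")
    edges = np.arange(window[0], window[1] + bin_ms * 0.5, bin_ms)
    counts, _ = np.histogram(events.times, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (bin_ms / 1000.0)


def spike_fraction_by_isi(
    events: EventSeries,
    stimulus_times,
    stimulus_labels,
    response_window: float = 10.0,
) -> dict:
    """Percentage of assigned spikes following stimuli of each ISI label.

    Each spike is assigned to the nearest preceding stimulus if it falls
    within ``response_window`` ms of it; other spikes are counted as
    unassigned.  Percentages sum to 100 over assigned spikes.
    """
    st = np.asarray(stimulus_times, dtype=float)
    labels = list(stimulus_labels)
    if st.size != len(labels):
        raise AnalysisError("stimulus times and labels must align")
    order = np.argsort(st)
    st = st[order]
    labels = [labels[k] for k in order]
    counts: dict = {lab: 0 for lab in dict.fromkeys(labels)}
    unassigned = 0
    for t in events.times:
        k = int(np.searchsorted(st, t, side="right")) - 1
        if k >= 0 and t - st[k] <= response_window:
            counts[labels[k]] += 1
        else:
            unassigned += 1
    total = sum(counts.values())
    pct = {lab: (100.0 * c / total if total else 0.0)
           for lab, c in counts.items()}
    return {"percent": pct, "assigned": total, "unassigned": unassigned,
            "empty": total == 0}


def subthreshold_from_spiking(
    trace: TraceRecord,
    threshold: float = -10.0,
    excision_half_width: float = 2.0,
    median_width: float = 5.0,
) -> tuple[TraceRecord, float]:
    """Spike-filtered subthreshold voltage.

    Removes ±``excision_half_width`` ms around each detected spike peak,
    linearly interpolates across the gaps, then applies a running median of
    ``median_width`` ms.  Returns the filtered trace and its mean (mV).
    """
    spikes = detect_spikes(trace, threshold=threshold)
    v = trace.samples.copy()
    t = trace.time
    keep = np.ones(v.size, dtype=bool)
    half = int(round(excision_half_width / trace.dt))
    for ts in spikes.times:
        i = trace.index_at(ts)
        keep[max(0, i - half): i + half + 1] = False
    if keep.sum() < 0.5 * v.size:
        raise AnalysisError("more than 50 % of the trace would be excised")
    v_interp = v.copy()
    if not keep.all():
        v_interp[~keep] = np.interp(t[~keep], t[keep], v[keep])
    k = int(round(median_width / trace.dt))
    k = k + 1 if k % 2 == 0 else k
    filtered = signal.medfilt(v_interp, kernel_size=max(k, 1))
    out = TraceRecord(dt=trace.dt, samples=filtered, kind="voltage",
                      site=trace.site, t0=trace.t0,
                      meta={**trace.meta, "spike_filtered": True})
    return out, float(np.mean(filtered))


def iei_band_probabilities(
    events: EventSeries,
    bands: BandDefinition = BandDefinition(),
) -> dict:
    """Probability that an inter-event interval falls in each frequency band.

    Each IEI (ms) maps to 1000/IEI Hz; intervals in inter-band gaps count as
    unassigned.  Assigned plus unassigned probabilities sum to 1 exactly.
    """
    if len(events) < 2:
        raise AnalysisError("need at least 2 events")
    ieis = events.intervals()
    freqs = 1000.0 / ieis
    counts = {name: 0 for name in bands.names()}
    unassigned = 0
    for f in freqs:
        name = bands.assign(float(f))
        if name is None:
            unassigned += 1
        else:
            counts[name] += 1
    n = freqs.size
    prob = {name: c / n for name, c in counts.items()}
    return {"probability": prob, "unassigned": unassigned / n,
            "n_intervals": n, "ieis_ms": ieis}


def fit_space_constant(distances, responses) -> SpaceConstantFit:
    """Least-squares fit of A·exp(−d/λ) to response-versus-distance data."""
    d = np.asarray(distances, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.size < 3:
        raise AnalysisError("need at least 3 points")
    if d.size != y.size:
        raise AnalysisError("distances and responses must align")
    slope = stats.linregress(d, y).slope
    if slope >= 0 or np.ptp(y) < 1e-12 * max(abs(y).max(), 1.0):
        return SpaceConstantFit(space_constant=math.inf,
                                amplitude=float(np.mean(y)),
                                r_squared=0.0, decaying=False)

    def model(x, a, lam):
        return a * np.exp(-x / lam)

    lam0 = max((d.max() - d.min()) / 3.0, 1e-6)
    popt, _ = optimize.curve_fit(model, d, y, p0=(float(y.max()), lam0),
                                 bounds=([0, 1e-9], [np.inf, np.inf]),
                                 maxfev=10000)
    resid = y - model(d, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return SpaceConstantFit(space_constant=float(popt[1]),
                            amplitude=float(popt[0]), r_squared=r2,
                            decaying=True)


def nernst_potential(
    c_out: float,
    c_in: float,
    temperature: float = 306.15,  # K — 33 °C, midpoint of the 32–34 °C range
    valence: int = 1,
) -> float:
    """Nernst equilibrium potential, mV: (RT/zF)·ln(c_out/c_in)."""
    if c_out <= 0 or c_in <= 0:
        raise AnalysisError("concentrations must be > 0")
    return (GAS_CONSTANT * temperature / (valence * FARADAY)
            * math.log(c_out / c_in) * 1e3)
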