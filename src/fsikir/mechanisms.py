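"""Membrane and synaptic conductance mechanisms.

The model cell is subthreshold and carries four kinds of conductance:

* two ohmic leaks, a K⁺ leak (e_K = −107 mV) and a Na⁺ leak (e_Na = +53 mV),
  which between them set the resting potential;
* an instantaneous inward-rectifier K⁺ conductance (Kir) whose open fraction
  is a Boltzmann function of voltage, decreasing with depolarization;
* double-exponential synaptic conductances (e_syn = 0 mV);
* optional fluctuating background excitatory/inhibitory conductances
  modelled as Ornstein–Uhlenbeck processes (point-conductance noise).

Densities are S/cm², point conductances µS, voltages mV, times ms.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

__all__ = [
    "LeakSpec",
    "KirSpec",
    "SynapseSpec",
    "NoiseProcess",
    "NoiseSpec",
    "Mechanisms",
    "kir_open_fraction",
    "synaptic_conductance",
    "synaptic_peak_time",
    "ou_conductance_step",
]

#: Reversal potential of the original single passive mechanism that the
#: two-leak split replaces (documentation constant, mV).
ORIGINAL_PASSIVE_REVERSAL = -61.6229


@dataclass(frozen=True)
class LeakSpec:
    """Ohmic K⁺ and Na⁺ leak densities and reversals."""

    g_k_density: float  # S/cm²
    g_na_density: float  # S/cm²
    e_k: float = -107.0  # mV
    e_na: float = 53.0  # mV

    def __post_init__(self) -> None:
        if self.g_k_density < 0 or self.g_na_density < 0:
            raise ValueError("leak densities must be >= 0")
        if not self.e_k < self.e_na:
            raise ValueError("e_K must be below e_Na")


@dataclass(frozen=True)
class KirSpec:
    """Instantaneous Boltzmann inward rectifier.

    The open fraction 1/(1+exp((v−v_half)/k_slope)) is 1 far below e_K and
    0 far above, producing the characteristic large inward / small outward
    limbs of the subtracted ramp current.
    """

    g_density: float  # S/cm², maximal (fully open) density
    e_k: float = -107.0
    v_half: float = -85.0  # mV
    k_slope: float = 12.0  # mV, > 0

    def __post_init__(self) -> None:
        if self.g_density < 0:
            raise ValueError("Kir density must be >= 0")
        if self.k_slope <= 0:
            raise ValueError("k_slope must be > 0")


def kir_open_fraction(v, spec: KirSpec):
    """Open fraction of the Kir conductance at voltage *v* (mV).

    Strictly decreasing in v, 0.5 at ``v_half``; accepts scalars or arrays.
    """
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - spec.v_half) / spec.k_slope))


@dataclass(frozen=True)
class SynapseSpec:
    """Double-exponential conductance synapse on one compartment.

    ``weight`` is the peak conductance in µS (the difference of exponentials
    is renormalized so its maximum equals the weight).  Multiple onsets sum
    linearly.
    """

    compartment: int
    tau_rise: float  # ms
    tau_decay: float  # ms
    weight: float  # µS, peak conductance
    e_syn: float = 0.0  # mV
    onsets: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def peak_norm(self) -> float:
        """max_t (exp(−t/τd) − exp(−t/τr)); divides the raw difference so the
        peak equals ``weight``."""
        tp = synaptic_peak_time(self.tau_rise, self.tau_decay)
        return math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise)


def synaptic_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the maximum of exp(−t/τd) − exp(−t/τr):
    (τr·τd/(τd−τr))·ln(τd/τr)."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def synaptic_conductance(t_since_onset, spec: SynapseSpec):
    """Conductance (µS) of a single event *t_since_onset* ms after onset.

    Zero at onset, peaks at ``weight``; callers superpose events linearly.
    """
    t = np.asarray(t_since_onset, dtype=float)
    g = (np.exp(-t / spec.tau_decay) - np.exp(-t / spec.tau_rise)) / spec.peak_norm
    return spec.weight * np.where(t >= 0, g, 0.0)


@dataclass(frozen=True)
class NoiseProcess:
    """One Ornstein–Uhlenbeck background conductance on one compartment."""

    compartment: int
    g0: float  # µS, stationary mean
    sigma: float  # µS, stationary SD
    tau: float  # ms, correlation time
    e_rev: float  # mV

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sigma < 0 or self.g0 < 0:
            raise ValueError("g0 and sigma must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Point-conductance background noise: paired excitatory and inhibitory
    OU conductances on a set of target compartments.

    ``scale`` multiplies the means and SDs of every process; it is the handle
    the protocols use to push the model's input resistance toward in-vivo
    values.  Defaults for reversals and correlation times follow the
    point-conductance literature: e_exc = 0 mV, e_inh = −75 mV,
    tau_exc = 2.7 ms, tau_inh = 10.5 ms.
    """

    targets: tuple[int, ...]
    g0_exc: float = 0.0121  # µS
    sigma_exc: float = 0.003
    tau_exc: float = 2.7
    e_exc: float = 0.0
    g0_inh: float = 0.0573  # µS
    sigma_inh: float = 0.0066
    tau_inh: float = 10.5
    e_inh: float = -75.0
    scale: float = 1.0
    seed: int = 0

    def processes(self) -> tuple[NoiseProcess, ...]:
        """Expand into per-compartment OU processes, scale applied to means
        and SDs (per-target conductance split evenly across targets)."""
        n = max(len(self.targets), 1)
        out = []
        for c in self.targets:
            out.append(NoiseProcess(c, self.scale * self.g0_exc / n,
                                    self.scale * self.sigma_exc / math.sqrt(n),
                                    self.tau_exc, self.e_exc))
            out.append(NoiseProcess(c, self.scale * self.g0_inh / n,
                                    self.scale * self.sigma_inh / math.sqrt(n),
                                    self.tau_inh, self.e_inh))
        return tuple(out)


def ou_conductance_step(g: float, dt: float, g0: float, sigma: float,
                        tau: float, rng: np.random.Generator) -> float:
    """Exact-discretization OU update, clipped at zero.

    g' = g0 + (g − g0)·e^(−dt/τ) + σ·sqrt(1 − e^(−2dt/τ))·N(0,1)
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rho = math.exp(-dt / tau)
    g_new = g0 + (g - g0) * rho + sigma * math.sqrt(1.0 - rho * rho) * rng.standard_normal()
    return max(g_new, 0.0)


@dataclass(frozen=True)
class Mechanisms:
    """Bundle of everything the cable engine inserts into a compartment tree.

    ``k_scale`` holds a per-compartment multiplicative factor applied to the
    5HT-sensitive K⁺ pool (K leak + Kir by default; Kir only if
    ``scale_kir_only``); protocols use it for uniform, scoped or spatially
    graded conductance reductions.
    """

    leak: LeakSpec
    kir: KirSpec
    synapses: tuple[SynapseSpec, ...] = ()
    noise: NoiseSpec | None = None
    k_scale: tuple[float, ...] | None = None  # per-compartment, default all 1
    scale_kir_only: bool = False

    def with_k_scale(self, scale) -> "Mechanisms":
        return replace(self, k_scale=tuple(float(s) for s in scale))

    def with_uniform_reduction(self, f: float, n_compartments: int,
                               mask=None) -> "Mechanisms":
        """Scale the K⁺ pool by (1−f) in masked compartments (all if None)."""
        base = list(self.k_scale) if self.k_scale is not None else [1.0] * n_compartments
        for i in range(n_compartments):
            if mask is None or mask[i]:
                base[i] *= (1.0 - f)
        return self.with_k_scale(base)
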