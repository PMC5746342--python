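"""Cable engine: integrate the branched-cable equation on a compartment tree.

Supports current clamp (somatic step currents plus synaptic onsets plus
optional background noise) and ideal somatic voltage clamp (linear ramp
commands, zero series resistance).  Integration is semi-implicit backward
Euler with a tree-ordered (Hines) solve, dt default 0.025 ms; see
``_kernel.integrate`` for the numerics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import integrate, steady_state_picard
from .mechanisms import Mechanisms, kir_open_fraction
from .morphology import CompartmentTree
from .records import IVCurve, TraceRecord

__all__ = [
    "EngineConfig",
    "StepStimulus",
    "IntegrationError",
    "run_current_clamp",
    "run_voltage_clamp_ramp",
    "measure_resting_state",
]


class IntegrationError(RuntimeError):
    """Numerical divergence (non-finite voltage) during integration."""


@dataclass(frozen=True)
class EngineConfig:
    """Solver configuration.

    ``temperature_c`` is documentation only (the model has no temperature-
    dependent rates); the recording temperature it mirrors is 32–34 °C.
    """

    dt: float = 0.025  # ms
    cm: float = 1.0  # µF/cm²
    temperature_c: float = 33.0

    def __post_init__(self) -> None:
        if not 0 < self.dt <= 0.1:
            raise ValueError("dt must be in (0, 0.1] ms")
        if self.cm <= 0:
            raise ValueError("cm must be > 0")


@dataclass(frozen=True)
class StepStimulus:
    """Piecewise-constant somatic current step, nA."""

    t_start: float
    t_stop: float
    amplitude: float  # nA

    def __post_init__(self) -> None:
        if self.t_stop <= self.t_start:
            raise ValueError("t_stop must exceed t_start")


def _assemble(tree: CompartmentTree, mech: Mechanisms, config: EngineConfig):
    """Per-compartment solver arrays in µS / nF from densities in S/cm²."""
    n = len(tree)
    parent = np.array([c.parent_index for c in tree.compartments], dtype=np.int64)
    area = np.array([c.area for c in tree.compartments])  # µm²
    cap = config.cm * area * 1e-5  # nF
    g_k = mech.leak.g_k_density * area * 1e-2  # µS
    g_na = mech.leak.g_na_density * area * 1e-2
    g_kir = mech.kir.g_density * area * 1e-2
    if mech.k_scale is not None:
        scale = np.asarray(mech.k_scale, dtype=float)
        if scale.shape != (n,):
            raise ValueError("k_scale length must match compartment count")
        g_kir = g_kir * scale
        if not mech.scale_kir_only:
            g_k = g_k * scale
    a_coup = np.zeros(n)
    for i in range(1, n):
        a_coup[i] = 1.0 / tree.coupling_resistance(i)  # µS
    return parent, a_coup, cap, g_k, g_na, g_kir


def _synapse_arrays(mech: Mechanisms):
    syns = mech.synapses
    ns = len(syns)
    syn_comp = np.array([s.compartment for s in syns], dtype=np.int64)
    syn_w = np.array([s.weight for s in syns])
    syn_tr = np.array([s.tau_rise for s in syns])
    syn_td = np.array([s.tau_decay for s in syns])
    syn_norm = np.array([s.peak_norm for s in syns])
    syn_esyn = np.array([s.e_syn for s in syns])
    on_start = np.zeros(ns + 1, dtype=np.int64)
    times = []
    for k, s in enumerate(syns):
        times.extend(s.onsets)
        on_start[k + 1] = len(times)
    syn_on_times = np.array(times, dtype=float) if times else np.zeros(0)
    return syn_comp, syn_w, syn_tr, syn_td, syn_norm, syn_esyn, on_start, syn_on_times


def _noise_arrays(mech: Mechanisms, n_steps: int, seed: int | None):
    if mech.noise is None or mech.noise.scale == 0.0 or not mech.noise.targets:
        z = np.zeros(0)
        return (np.zeros(0, dtype=np.int64), z.copy(), z.copy(), z.copy(),
                np.ones(0), z.copy(), np.zeros((0, n_steps)))
    procs = mech.noise.processes()
    nn = len(procs)
    comp = np.array([p.compartment for p in procs], dtype=np.int64)
    g0 = np.array([p.g0 for p in procs])
    sigma = np.array([p.sigma for p in procs])
    tau = np.array([p.tau for p in procs])
    erev = np.array([p.e_rev for p in procs])
    rng = np.random.default_rng(mech.noise.seed if seed is None else seed)
    normals = rng.standard_normal((nn, n_steps))
    # start each process at a draw from its stationary distribution
    g_init = np.clip(g0 + sigma * rng.standard_normal(nn), 0.0, None)
    return comp, g_init, g0, sigma, tau, erev, normals


def initial_voltage(tree: CompartmentTree, mech: Mechanisms,
                    v_guess: float = -70.0) -> float:
    """Fixed-point estimate of the uniform resting potential (used only to
    seed the integrator; the settle period does the real work)."""
    parent, a_coup, cap, g_k, g_na, g_kir = _assemble(tree, mech, EngineConfig())
    v = v_guess
    for _ in range(200):
        m = float(np.mean(kir_open_fraction(v, mech.kir)))
        gk = g_k.sum() + m * g_kir.sum()
        gna = g_na.sum()
        v_new = (gk * mech.leak.e_k + gna * mech.leak.e_na) / (gk + gna)
        if abs(v_new - v) < 1e-10:
            break
        v = 0.5 * v + 0.5 * v_new
    return v


def run_current_clamp(
    tree: CompartmentTree,
    mech: Mechanisms,
    duration: float,
    stimuli: tuple[StepStimulus, ...] = (),
    config: EngineConfig = EngineConfig(),
    record: tuple[int, ...] = (0,),
    v_init: float | np.ndarray | None = None,
    noise_seed: int | None = None,
) -> dict[int, TraceRecord]:
    """Current-clamp run; returns voltage traces at the requested compartments.

    Synaptic onsets are taken from ``mech.synapses``; ``stimuli`` are somatic
    current steps.  Deterministic given ``noise_seed`` (or the seed stored in
    the noise spec).
    """
    dt = config.dt
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one time step")
    for st in stimuli:
        if st.t_start < 0 or st.t_stop > duration + 1e-9:
            raise ValueError("stimulus outside the simulation window")
    parent, a_coup, cap, g_k, g_na, g_kir = _assemble(tree, mech, config)
    n = len(tree)
    i_inj = np.zeros(n_steps)
    tgrid = (np.arange(n_steps) + 1) * dt  # current applied during each step
    for st in stimuli:
        i_inj[(tgrid > st.t_start) & (tgrid <= st.t_stop)] += st.amplitude
    if v_init is None:
        v = np.full(n, initial_voltage(tree, mech))
    elif np.isscalar(v_init):
        v = np.full(n, float(v_init))
    else:
        v = np.asarray(v_init, dtype=float).copy()
    rec_idx = np.asarray(record, dtype=np.int64)
    syn = _synapse_arrays(mech)
    noi = _noise_arrays(mech, n_steps, noise_seed)
    v_rec, _, bad_step = integrate(
        parent, a_coup, cap, g_k, g_na, g_kir,
        mech.leak.e_k, mech.leak.e_na, mech.kir.v_half, mech.kir.k_slope,
        *syn, *noi, i_inj, False, np.zeros(n_steps + 1), v, dt, rec_idx,
    )
    if bad_step >= 0:
        raise IntegrationError(f"non-finite voltage at step {bad_step}")
    return {
        int(ci): TraceRecord(dt=dt, samples=v_rec[:, k], kind="voltage",
                             site=f"comp{int(ci)}")
        for k, ci in enumerate(rec_idx)
    }


def run_voltage_clamp_ramp(
    tree: CompartmentTree,
    mech: Mechanisms,
    v_start: float = -150.0,
    v_end: float = -50.0,
    duration: float = 3000.0,
    config: EngineConfig = EngineConfig(),
    settle: float = 200.0,
    noise_seed: int | None = None,
    condition: str = "",
) -> IVCurve:
    """Ideal somatic voltage clamp through a linear ramp command.

    The soma is held at ``v_start`` for ``settle`` ms (discarded), then
    ramped linearly to ``v_end`` over ``duration`` ms.  The clamp current is
    the somatic membrane current plus the axial current leaving the soma plus
    the capacitive charging current of the command.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    dt = config.dt
    n_settle = int(round(settle / dt))
    n_ramp = int(round(duration / dt))
    n_steps = n_settle + n_ramp
    vcmd = np.empty(n_steps + 1)
    vcmd[: n_settle + 1] = v_start
    vcmd[n_settle:] = np.linspace(v_start, v_end, n_ramp + 1)
    parent, a_coup, cap, g_k, g_na, g_kir = _assemble(tree, mech, config)
    n = len(tree)
    v = np.full(n, float(v_start))  # guard against int inputs: the solver
    syn = _synapse_arrays(mech)     # state must be float64
    noi = _noise_arrays(mech, n_steps, noise_seed)
    _, i_clamp, bad_step = integrate(
        parent, a_coup, cap, g_k, g_na, g_kir,
        mech.leak.e_k, mech.leak.e_na, mech.kir.v_half, mech.kir.k_slope,
        *syn, *noi, np.zeros(n_steps), True, vcmd, v, dt,
        np.zeros(1, dtype=np.int64),
    )
    if bad_step >= 0:
        raise IntegrationError(f"non-finite voltage at step {bad_step}")
    # one (V, I) pair per ramp step, V strictly increasing
    v_grid = vcmd[n_settle + 1:]
    i_ramp = i_clamp[n_settle:]
    return IVCurve(v=v_grid, i=i_ramp, condition=condition,
                   ramp_duration=duration)


def solve_steady_state(
    tree: CompartmentTree,
    mech: Mechanisms,
    config: EngineConfig = EngineConfig(),
    i_inj: float = 0.0,
    v_guess: float | np.ndarray = -70.0,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> np.ndarray:
    """Steady-state voltages with a constant somatic current (nA).

    Picard iteration: the Kir open fraction is frozen at the previous
    iterate, the resulting linear resistive network is solved exactly by
    tree-ordered elimination, and the two alternate until the voltage update
    falls below ``tol``.  Equivalent to an infinitely long settle of the time
    integrator (synapses and noise excluded).
    """
    parent, a_coup, cap, g_k, g_na, g_kir = _assemble(tree, mech, config)
    n = len(tree)
    v = np.full(n, float(v_guess)) if np.isscalar(v_guess) \
        else np.asarray(v_guess, dtype=float).copy()
    n_iter = steady_state_picard(parent, a_coup, g_k, g_na, g_kir,
                                 mech.leak.e_k, mech.leak.e_na,
                                 mech.kir.v_half, mech.kir.k_slope,
                                 i_inj, v, tol, max_iter)
    if n_iter < 0:
        raise IntegrationError("steady state did not converge")
    return v


def measure_resting_state(
    tree: CompartmentTree,
    mech: Mechanisms,
    config: EngineConfig = EngineConfig(),
    settle: float = 500.0,
    step_amplitude: float = -0.05,  # nA
    step_duration: float = 500.0,
    noise_seed: int | None = None,
    rest_tolerance: float = 0.05,  # mV, drift bound for noise-free runs
) -> tuple[float, float]:
    """Resting potential and input resistance at the soma.

    Vm is the mean somatic voltage over the final 100 ms of the settle
    period; Rin is ΔV_steady / |step| for a −50 pA (default) step, with
    ΔV_steady taken over the final 100 ms of the step (Ohm's law).
    Returns ``(vm_mV, rin_MΩ)``.
    """
    duration = settle + step_duration
    step = StepStimulus(settle, settle + step_duration, step_amplitude)
    traces = run_current_clamp(tree, mech, duration, (step,), config,
                               record=(0,), noise_seed=noise_seed)
    tr = traces[0]
    pre = tr.window(settle - 100.0, settle)
    vm = float(np.mean(pre))
    noisy = mech.noise is not None and mech.noise.scale > 0 and mech.noise.targets
    if not noisy and float(np.max(pre) - np.min(pre)) > rest_tolerance:
        raise IntegrationError("resting potential did not converge during settle")
    steady = tr.window(duration - 100.0, duration)
    dv = float(np.mean(steady)) - vm
    rin = dv / step_amplitude  # mV / nA = MΩ
    return vm, rin
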