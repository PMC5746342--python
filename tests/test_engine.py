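import math
from dataclasses import replace

import numpy as np
import pytest

from conftest import make_single_compartment
from fsikir.engine import (EngineConfig, StepStimulus, measure_resting_state,
                           run_current_clamp, run_voltage_clamp_ramp,
                           solve_steady_state)
from fsikir.mechanisms import KirSpec, LeakSpec, Mechanisms, NoiseSpec, SynapseSpec
from fsikir.model import CellModel, default_model
from fsikir.morphology import Morphology, Section, build_reduced_fsi, discretize


class TestCurrentClamp:
    def test_rc_relaxation_matches_closed_form(self, single_compartment):
        """Single passive compartment under a step relaxes as
        V∞ + (V0−V∞)·exp(−t/τm) within 1 % of the deflection at dt=0.025."""
        m = single_compartment
        area_cm2 = m.tree.total_area() * 1e-8
        g_tot = (1.5e-4 + 0.45e-4) * area_cm2 * 1e6  # µS
        c_tot = 1.0 * area_cm2 * 1e3  # nF
        tau = c_tot / g_tot
        v_rest = (1.5 * -107 + 0.45 * 53) / 1.95
        tr = run_current_clamp(m.tree, m.mech, 300.0,
                               (StepStimulus(100.0, 300.0, -0.05),),
                               m.config)[0]
        v_inf = v_rest - 0.05 / g_tot
        t = tr.time
        sel = (t > 100.0) & (t <= 300.0)
        pred = v_inf + (v_rest - v_inf) * np.exp(-(t[sel] - 100.0) / tau)
        err = np.max(np.abs(tr.samples[sel] - pred)) / abs(v_inf - v_rest)
        assert err < 0.01

    def test_sealed_cable_attenuation_matches_cosh(self, soma_dendrite):
        """Steady-state voltage profile along a sealed passive cable follows
        cosh((L−x)/λ)/cosh(L/λ) within 2 %."""
        m = soma_dendrite
        rec = tuple(range(len(m.tree)))
        traces = run_current_clamp(m.tree, m.mech, 600.0,
                                   (StepStimulus(100.0, 600.0, 0.05),),
                                   m.config, record=rec, v_init=-107.0)
        rm = 1.0 / 2e-4  # Ω·cm²
        lam = math.sqrt(rm * 1.5e-4 / (4 * 172.0)) * 1e4  # µm
        L = 200.0
        dend = [c for c in m.tree.compartments if c.section_id == 1]
        x0 = m.tree.path_distance(dend[0].index)
        u0 = traces[dend[0].index].samples[-1] + 107.0
        ref = math.cosh((L - x0) / lam)
        for c in dend[1:]:
            x = m.tree.path_distance(c.index)
            u = traces[c.index].samples[-1] + 107.0
            pred = math.cosh((L - x) / lam) / ref
            assert u / u0 == pytest.approx(pred, rel=0.02)

    def test_rest_is_conductance_weighted_mean_without_kir(self):
        m = default_model(g_k_density=1.5e-4, g_na_density=0.45e-4)
        vm, _ = measure_resting_state(m.tree, m.mech, m.config)
        expected = (1.5e-4 * -107 + 0.45e-4 * 53) / 1.95e-4
        assert vm == pytest.approx(expected, abs=1e-6)

    def test_stimulus_outside_window_rejected(self, single_compartment):
        m = single_compartment
        with pytest.raises(ValueError):
            run_current_clamp(m.tree, m.mech, 100.0,
                              (StepStimulus(50.0, 200.0, 0.1),), m.config)

    def test_charge_conservation_two_compartments(self):
        """Discrete backward-Euler balance: C·ΔV/dt + I_mem = I_axial for
        the child compartment at every step."""
        morph = Morphology((Section(0, -1, "soma", 20, 10),
                            Section(1, 0, "dendrite", 20, 2)))
        tree = discretize(morph, max_compartment_length=25.0)
        assert len(tree) == 2
        mech = Mechanisms(leak=LeakSpec(2e-4, 0.5e-4), kir=KirSpec(0.0))
        cfg = EngineConfig()
        traces = run_current_clamp(tree, mech, 50.0,
                                   (StepStimulus(10.0, 50.0, 0.1),), cfg,
                                   record=(0, 1), v_init=-70.0)
        v0, v1 = traces[0].samples, traces[1].samples
        c1 = tree.compartments[1]
        cap = 1.0 * c1.area * 1e-5  # nF
        gk = 2e-4 * c1.area * 1e-2
        gna = 0.5e-4 * c1.area * 1e-2
        a = 1.0 / tree.coupling_resistance(1)
        dt = cfg.dt
        for k in range(1, v1.size):
            lhs = cap * (v1[k] - v1[k - 1]) / dt \
                + gk * (v1[k] + 107) + gna * (v1[k] - 53)
            rhs = a * (v0[k] - v1[k])
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestConvergenceAndDeterminism:
    def test_dt_halving_changes_voltage_below_0p05mV(self):
        m = default_model(g_kir_density=3e-4)
        syns = (SynapseSpec(compartment=50, tau_rise=0.5, tau_decay=14.0,
                            weight=1e-3, onsets=(50.0,)),)
        out = {}
        for dt in (0.05, 0.025):
            mm = replace(m, mech=replace(m.mech, synapses=syns),
                         config=EngineConfig(dt=dt))
            tr = run_current_clamp(mm.tree, mm.mech, 150.0, (), mm.config,
                                   v_init=-71.0)[0]
            out[dt] = np.interp([40.0, 60.0, 100.0, 150.0], tr.time,
                                tr.samples)
        assert np.max(np.abs(out[0.05] - out[0.025])) < 0.05

    def test_spatial_convergence_on_rediscretization(self):
        morph = build_reduced_fsi()
        vms = []
        for mcl in (10.0, 5.0):
            tree = discretize(morph, max_compartment_length=mcl)
            mech = Mechanisms(leak=LeakSpec(2.4e-4, 1.0e-4),
                              kir=KirSpec(g_density=4e-4))
            vms.append(solve_steady_state(tree, mech, EngineConfig())[0])
        assert abs(vms[0] - vms[1]) < 0.05

    def test_noise_free_runs_bit_identical(self, single_compartment):
        m = single_compartment
        a = run_current_clamp(m.tree, m.mech, 100.0,
                              (StepStimulus(20.0, 80.0, -0.05),), m.config)[0]
        b = run_current_clamp(m.tree, m.mech, 100.0,
                              (StepStimulus(20.0, 80.0, -0.05),), m.config)[0]
        assert np.array_equal(a.samples, b.samples)

    def test_noisy_runs_bit_identical_given_seed(self):
        m = default_model()
        m = m.with_noise(NoiseSpec(targets=m.noise_targets_default(),
                                   scale=0.3, seed=5))
        a = run_current_clamp(m.tree, m.mech, 100.0, (), m.config,
                              v_init=-70.0, noise_seed=5)[0]
        b = run_current_clamp(m.tree, m.mech, 100.0, (), m.config,
                              v_init=-70.0, noise_seed=5)[0]
        assert np.array_equal(a.samples, b.samples)


class TestVoltageClamp:
    def test_linear_leak_gives_straight_iv(self, single_compartment):
        m = single_compartment
        iv = run_voltage_clamp_ramp(m.tree, m.mech, -150.0, -50.0, 3000.0,
                                    m.config)
        area_cm2 = m.tree.total_area() * 1e-8
        g_tot = 1.95e-4 * area_cm2 * 1e6  # µS
        slope, intercept = np.polyfit(iv.v, iv.i, 1)
        assert slope == pytest.approx(g_tot, rel=0.01)
        v_rest = (1.5 * -107 + 0.45 * 53) / 1.95
        assert -intercept / slope == pytest.approx(v_rest, abs=0.2)

    def test_clamp_at_rest_draws_no_current(self, single_compartment):
        m = single_compartment
        v_rest = (1.5 * -107 + 0.45 * 53) / 1.95
        iv = run_voltage_clamp_ramp(m.tree, m.mech, v_rest, v_rest + 1e-9,
                                    500.0, m.config)
        assert abs(iv.i[-1]) < 1e-3  # < 1 pA

    def test_kir_makes_iv_sublinear(self):
        """With leak + Kir the I–V slope drops through the Kir activation
        range and stays below the slope at E_K up to −50 mV; the zero
        crossing lies between e_K and e_Na."""
        m = make_single_compartment(g_kir=4e-4)
        iv = run_voltage_clamp_ramp(m.tree, m.mech, -150.0, -50.0, 3000.0,
                                    m.config)
        vg = np.arange(-107.0, -49.9, 5.0)
        ig = np.interp(vg, iv.v, iv.i)
        slopes = np.diff(ig) / 5.0
        activation = slopes[: 6]  # −107 … −77 mV
        assert np.all(np.diff(activation) < 0)
        assert np.all(slopes[1:] < slopes[0])
        crossing = np.interp(0.0, iv.i, iv.v)
        assert -107.0 < crossing < 53.0

    def test_kir_difference_current_reverses_at_ek_isopotential(self):
        """Scaling Kir by 0.3 and subtracting cancels every common-mode
        component of an isopotential cell: the difference reverses at e_K."""
        from fsikir.ephys import estimate_reversal, iv_difference
        m = make_single_compartment(g_kir=4e-4)
        reduced = replace(m, mech=replace(m.mech, scale_kir_only=True)) \
            .with_reduction(0.7, scope="both")
        iv_a = run_voltage_clamp_ramp(m.tree, m.mech, -150, -50, 3000.0)
        iv_b = run_voltage_clamp_ramp(reduced.tree, reduced.mech,
                                      -150, -50, 3000.0)
        rev = estimate_reversal(iv_difference(iv_a, iv_b))
        assert rev == pytest.approx(-107.0, abs=1e-3)


class TestMeasureRestingState:
    def test_ohms_law_example(self):
        """g_total = 10.75 nS → Rin ≈ 93 MΩ."""
        area_cm2 = math.pi * 15 * 15 * 1e-8
        density = 10.75e-9 / area_cm2  # S/cm² total
        m = make_single_compartment(g_k=density * 0.775,
                                    g_na=density * 0.225)
        _, rin = measure_resting_state(m.tree, m.mech, m.config)
        assert rin == pytest.approx(93.0, rel=0.01)

    def test_doubling_densities_halves_rin(self):
        m1 = make_single_compartment(g_k=1.5e-4, g_na=0.45e-4)
        m2 = make_single_compartment(g_k=3.0e-4, g_na=0.9e-4)
        _, r1 = measure_resting_state(m1.tree, m1.mech, m1.config)
        _, r2 = measure_resting_state(m2.tree, m2.mech, m2.config)
        assert r2 == pytest.approx(r1 / 2, rel=0.01)

    def test_steady_state_solver_matches_step_protocol(self):
        m = default_model(g_kir_density=4e-4)
        vm_p, rin_p = measure_resting_state(m.tree, m.mech, m.config)
        v0 = solve_steady_state(m.tree, m.mech, m.config)
        v1 = solve_steady_state(m.tree, m.mech, m.config, i_inj=-0.05)
        assert vm_p == pytest.approx(v0[0], abs=1e-4)
        assert rin_p == pytest.approx((v1[0] - v0[0]) / -0.05, rel=1e-4)
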