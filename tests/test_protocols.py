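from dataclasses import replace

import numpy as np
import pytest

from fsikir.mechanisms import NoiseSpec
from fsikir.protocols import (epsp_response, run_gk_sweep,
                              run_local_modulation_scan,
                              run_noise_replicates, run_summation,
                              scale_noise_to_rin, summation_comparison)


class TestGkSweep:
    @pytest.fixture(scope="class")
    def sweeps(self, calibrated, syn_kwargs):
        fr = [0.0, 0.05, 0.10, 0.15, 0.20]
        return {scope: run_gk_sweep(calibrated.baseline, fr, scope=scope,
                                    **syn_kwargs)
                for scope in ("soma", "dendrites", "both")}

    def test_zero_fraction_equals_baseline(self, sweeps, targets):
        for r in sweeps.values():
            assert r.vm[0] == pytest.approx(targets.vm_rest, abs=0.05)
            assert r.rin[0] == pytest.approx(targets.rin, abs=0.2)

    def test_dendritic_reduction_prolongs_tau_monotonically(self, sweeps):
        tau = sweeps["dendrites"].epsp_tau
        assert all(b > a for a, b in zip(tau, tau[1:]))

    def test_soma_only_effect_much_smaller_than_dendritic(self, sweeps):
        """The tau prolongation is a dendritic effect: at matched f the
        somatic-only reduction produces a small fraction of it."""
        d_tau = sweeps["dendrites"].epsp_tau[-1] - sweeps["dendrites"].epsp_tau[0]
        s_tau = sweeps["soma"].epsp_tau[-1] - sweeps["soma"].epsp_tau[0]
        assert d_tau > 1.0
        assert s_tau < 0.5 * d_tau

    def test_vm_and_rin_monotone_in_reduction(self, sweeps):
        for r in sweeps.values():
            assert all(b > a for a, b in zip(r.vm, r.vm[1:]))
            assert all(b > a for a, b in zip(r.rin, r.rin[1:]))

    def test_amplitude_stable_while_local_amplitude_falls(self, calibrated,
                                                          syn_kwargs):
        """At the calibrated reduction the somatic EPSP changes ≤ 10 % while
        the local dendritic EPSP shrinks."""
        f = calibrated.result.reduction_fraction
        b = epsp_response(calibrated.baseline, **syn_kwargs)
        m = epsp_response(calibrated.baseline.with_reduction(f), **syn_kwargs)
        assert abs(m.somatic_amplitude / b.somatic_amplitude - 1) <= 0.10
        assert m.local_amplitude / b.local_amplitude < 1.0

    def test_invalid_fractions_rejected(self, calibrated):
        with pytest.raises(ValueError):
            run_gk_sweep(calibrated.baseline, [0.99], scope="both")


class TestSummation:
    def test_near_synchronous_compound_sublinear(self, calibrated,
                                                 syn_kwargs):
        """At 0.12 ms ISI the compound amplitude is below 5× a single EPSP
        (driving-force saturation toward e_syn = 0)."""
        single = epsp_response(calibrated.baseline, **syn_kwargs)
        amp, _ = run_summation(calibrated.baseline, 0.12, **syn_kwargs)
        assert amp <= 5 * single.somatic_amplitude

    def test_enhancement_peaks_in_gamma_band(self, calibrated, syn_kwargs):
        res = summation_comparison(calibrated.baseline, calibrated.reduced,
                                   [0.12, 5.0, 10.0, 20.0, 50.0],
                                   **syn_kwargs)
        assert res.argmax_isi() in (10.0, 20.0)
        i10 = list(res.isis).index(10.0)
        i50 = list(res.isis).index(50.0)
        assert res.amplitude_ratio[i50] < res.amplitude_ratio[i10]

    def test_ratio_approaches_single_epsp_ratio_at_large_isi(self,
                                                             calibrated,
                                                             syn_kwargs):
        b = epsp_response(calibrated.baseline, **syn_kwargs)
        r = epsp_response(calibrated.reduced, **syn_kwargs)
        single_ratio = r.somatic_amplitude / b.somatic_amplitude
        res = summation_comparison(calibrated.baseline, calibrated.reduced,
                                   [200.0], **syn_kwargs)
        assert res.amplitude_ratio[0] == pytest.approx(single_ratio,
                                                       rel=0.02)

    def test_reproducible_bit_exact(self, calibrated, syn_kwargs):
        noise = NoiseSpec(targets=calibrated.baseline.noise_targets_default(),
                          scale=0.2)
        m = calibrated.baseline.with_noise(noise)
        a = run_summation(m, 10.0, noise_seed=3, **syn_kwargs)
        b = run_summation(m, 10.0, noise_seed=3, **syn_kwargs)
        assert a == b


class TestNoise:
    def test_zero_scale_identical_to_noise_free(self, calibrated,
                                                syn_kwargs):
        m0 = calibrated.baseline
        noise = NoiseSpec(targets=m0.noise_targets_default(), scale=0.0)
        a = run_summation(m0, 10.0, **syn_kwargs)
        b = run_summation(m0.with_noise(noise), 10.0, noise_seed=1,
                          **syn_kwargs)
        assert a == pytest.approx(b, abs=1e-12)

    def test_rin_strictly_decreases_with_noise_scale(self, calibrated):
        m0 = calibrated.baseline
        noise = NoiseSpec(targets=m0.noise_targets_default())
        means = []
        for scale in (0.05, 0.15, 0.4):
            _, rins = run_noise_replicates(
                m0, replace(noise, scale=scale), n_replicates=3, base_seed=0)
            means.append(float(np.mean(rins)))
        assert means[0] > means[1] > means[2]

    def test_replicate_count_validated(self, calibrated):
        noise = NoiseSpec(targets=calibrated.baseline.noise_targets_default())
        with pytest.raises(ValueError):
            run_noise_replicates(calibrated.baseline, noise, n_replicates=0)


class TestLocalModulation:
    def test_zero_strength_zero_effect(self, calibrated):
        dv = run_local_modulation_scan(calibrated.baseline, [50.0, 150.0],
                                       extent=10.0, f=0.0)
        assert np.max(np.abs(dv)) < 1e-9

    def test_depolarization_decays_with_distance(self, calibrated):
        centers = [30.0, 70.0, 110.0, 150.0, 190.0]
        dv = run_local_modulation_scan(calibrated.baseline, centers,
                                       extent=10.0, f=0.9)
        assert np.all(dv > 0)
        assert all(b < a for a, b in zip(dv, dv[1:]))

    def test_iontophoresis_scale_depolarization_attainable(self, calibrated):
        """A ~1.2 mV somatic depolarization from purely dendritic
        modulation is reachable within the default parameter ranges."""
        best = max(
            float(np.max(run_local_modulation_scan(
                calibrated.baseline, [30.0, 50.0], extent=extent, f=0.9)))
            for extent in (10.0, 15.0))
        assert best >= 1.19

    def test_invalid_extent_rejected(self, calibrated):
        with pytest.raises(ValueError):
            run_local_modulation_scan(calibrated.baseline, [50.0],
                                      extent=0.0, f=0.5)
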