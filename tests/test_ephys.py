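import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsikir.ephys import (AnalysisError, BandDefinition, FitError,
                          charge_transfer, detect_spikes, estimate_reversal,
                          firing_rate_psth, fit_decay_tau, fit_space_constant,
                          iei_band_probabilities, input_resistance_from_step,
                          iv_difference, nernst_potential,
                          slope_conductance_change, spike_fraction_by_isi,
                          subthreshold_from_spiking, summation_metrics)
from fsikir.records import EventSeries, IVCurve, TraceRecord
from fsikir.synth import gen_epsp_trace, gen_spiking_trace, gen_step_trace


def exp_trace(tau=15.0, amp=2.0, baseline=-71.0, dt=0.1, duration=200.0,
              t_peak=20.0):
    t = np.arange(0.0, duration, dt)
    v = np.full_like(t, baseline)
    after = t >= t_peak
    v[after] += amp * np.exp(-(t[after] - t_peak) / tau)
    return TraceRecord(dt=dt, samples=v)


class TestFitDecayTau:
    def test_pure_exponential_self_fit(self):
        fit = fit_decay_tau(exp_trace(tau=15.0))
        assert fit.tau == pytest.approx(15.0, abs=0.1)
        assert fit.r_squared > 0.999

    @pytest.mark.parametrize("tau", [10.4, 14.7, 18.6])
    def test_synthetic_epsp_recovery(self, tau):
        tr, _ = gen_epsp_trace(tau_decay=tau, noise_sd=0.0, seed=0)
        fit = fit_decay_tau(tr)
        assert fit.tau == pytest.approx(tau, rel=0.05)

    def test_double_exponential_rise_excluded(self):
        tr, _ = gen_epsp_trace(tau_rise=2.0, tau_decay=15.0, noise_sd=0.0)
        fit = fit_decay_tau(tr)
        assert fit.tau == pytest.approx(15.0, rel=0.10)

    def test_non_decaying_segment_fails(self):
        t = np.arange(0.0, 100.0, 0.1)
        tr = TraceRecord(dt=0.1, samples=-71.0 + 0.01 * t)
        with pytest.raises(FitError):
            fit_decay_tau(tr)

    @given(st.floats(0.1, 50.0), st.floats(-30.0, 30.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_to_scale_and_offset(self, scale, offset):
        base = exp_trace(tau=12.0)
        scaled = TraceRecord(dt=base.dt,
                             samples=base.samples * scale + offset)
        f1 = fit_decay_tau(base)
        f2 = fit_decay_tau(scaled)
        assert f2.tau == pytest.approx(f1.tau, rel=1e-4)


class TestInputResistance:
    def test_ohms_law_arithmetic(self):
        """ΔV = −4.645 mV at −50 pA → 92.9 MΩ."""
        t = np.arange(0.0, 900.0, 0.1)
        v = np.full_like(t, -71.0)
        v[(t >= 200) & (t < 700)] -= 4.645
        tr = TraceRecord(dt=0.1, samples=v)
        rin = input_resistance_from_step(tr, -0.05, (200.0, 700.0))
        assert rin == pytest.approx(92.9, rel=1e-6)

    def test_zero_deflection_zero_rin(self):
        t = np.arange(0.0, 900.0, 0.1)
        tr = TraceRecord(dt=0.1, samples=np.full_like(t, -71.0))
        assert input_resistance_from_step(tr, -0.05, (200.0, 700.0)) == 0.0

    def test_synthetic_rc_recovery(self):
        tr, truth = gen_step_trace(rin=92.9, noise_sd=0.0)
        rin = input_resistance_from_step(tr, truth["step_amplitude"],
                                         truth["step_window"])
        assert rin == pytest.approx(92.9, rel=0.01)

    def test_short_step_warns(self):
        tr, truth = gen_step_trace(tau_m=50.0, step_window=(200.0, 320.0),
                                   duration=400.0)
        with pytest.warns(UserWarning, match="shorter"):
            input_resistance_from_step(tr, truth["step_amplitude"],
                                       (200.0, 320.0))

    def test_zero_step_rejected(self):
        tr, _ = gen_step_trace()
        with pytest.raises(AnalysisError):
            input_resistance_from_step(tr, 0.0, (200.0, 700.0))


class TestIvOperations:
    V = np.linspace(-150.0, -50.0, 201)

    def test_difference_of_identical_curves_is_zero(self):
        c = IVCurve(v=self.V, i=0.01 * (self.V + 61.0))
        d = iv_difference(c, c)
        assert np.all(d.i == 0.0)

    def test_conductance_difference(self):
        e = -99.0
        a = IVCurve(v=self.V, i=0.010 * (self.V - e))
        b = IVCurve(v=self.V, i=0.008 * (self.V - e))
        d = iv_difference(a, b)
        assert np.allclose(d.i, 0.002 * (self.V - e))
        assert estimate_reversal(d) == pytest.approx(e, abs=1e-9)

    def test_subtraction_commutes_with_interpolation_on_linear_curves(self):
        v2 = np.linspace(-150.0, -50.0, 157)
        a = IVCurve(v=self.V, i=0.01 * (self.V + 80.0))
        b = IVCurve(v=v2, i=0.004 * (v2 + 80.0))
        d = iv_difference(a, b)
        expected = 0.01 * (d.v + 80.0) - 0.004 * (d.v + 80.0)
        assert np.max(np.abs(d.i - expected)) < 1e-9

    def test_non_overlapping_grids_rejected(self):
        a = IVCurve(v=np.linspace(-150, -100, 50),
                    i=np.linspace(-1, 0, 50))
        b = IVCurve(v=np.linspace(-90, -50, 50), i=np.linspace(0, 1, 50))
        with pytest.raises(AnalysisError):
            iv_difference(a, b)

    def test_reversal_constructed_crossing(self):
        c = IVCurve(v=self.V, i=0.005 * (self.V + 99.0))
        assert estimate_reversal(c) == pytest.approx(-99.0, abs=1e-9)

    def test_reversal_outward_only_errors(self):
        c = IVCurve(v=self.V, i=np.abs(self.V + 100.0) + 0.1)
        with pytest.raises(AnalysisError):
            estimate_reversal(c)

    def test_slope_change_two_lines(self):
        a = IVCurve(v=self.V, i=0.010 * self.V)  # 10 nS
        b = IVCurve(v=self.V, i=0.008 * self.V + 0.3)  # 8 nS, offset
        d = slope_conductance_change(a, b, (-140.0, -60.0))
        assert d == pytest.approx(-0.002, abs=1e-12)

    def test_slope_invariant_to_offset(self):
        a = IVCurve(v=self.V, i=0.01 * self.V)
        b = IVCurve(v=self.V, i=0.01 * self.V + 5.0)
        assert slope_conductance_change(a, b, (-140.0, -60.0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_slope_recovery_on_noisy_line(self):
        rng = np.random.default_rng(1)
        sd = 0.01
        i = 0.01 * self.V + sd * rng.standard_normal(self.V.size)
        b = IVCurve(v=self.V, i=i)
        a = IVCurve(v=self.V, i=0.01 * self.V)
        keep = (self.V >= -140) & (self.V <= -60)
        n = keep.sum()
        sx = np.std(self.V[keep])
        se = sd / (sx * math.sqrt(n))
        d = slope_conductance_change(a, b, (-140.0, -60.0))
        assert abs(d) < 2 * se

    def test_too_few_points_rejected(self):
        a = IVCurve(v=self.V, i=0.01 * self.V)
        with pytest.raises(AnalysisError):
            slope_conductance_change(a, a, (-150.0, -149.0))


class TestChargeTransfer:
    def test_constant_current(self):
        t = np.arange(0.0, 1000.0 + 0.05, 0.1)
        tr = TraceRecord(dt=0.1, samples=np.full_like(t, 0.1),
                         kind="current")
        assert charge_transfer(tr) == pytest.approx(0.1, rel=1e-9)

    def test_zero_current(self):
        tr = TraceRecord(dt=0.1, samples=np.zeros(1001), kind="current")
        assert charge_transfer(tr) == 0.0

    def test_trapezoid_matches_analytic_sine(self):
        t = np.arange(0.0, 1000.0 + 0.05, 0.1)
        w = 2 * math.pi / 400.0
        tr = TraceRecord(dt=0.1, samples=np.sin(w * t), kind="current")
        analytic = (1 - math.cos(w * 1000.0)) / w / 1e3
        assert charge_transfer(tr) == pytest.approx(analytic, abs=1e-6)

    def test_iv_curve_needs_ramp_duration(self):
        c = IVCurve(v=np.linspace(-150, -50, 100), i=np.ones(100))
        with pytest.raises(AnalysisError):
            charge_transfer(c)


class TestSummationMetrics:
    def test_aligned_copies_scale_amplitude(self):
        tr, _ = gen_epsp_trace(onsets=(100.0,), amplitude=1.0, noise_sd=0.0)
        amp1, _ = summation_metrics(tr, [100.0])
        tr5 = TraceRecord(dt=tr.dt, samples=(tr.samples + 71.0) * 5 - 71.0)
        amp5, _ = summation_metrics(tr5, [100.0] * 5)
        assert amp5 == pytest.approx(5 * amp1, rel=1e-9)

    def test_integral_linearity_for_separated_events(self):
        one, _ = gen_epsp_trace(onsets=(100.0,), duration=1500.0,
                                noise_sd=0.0)
        _, int1 = summation_metrics(one, [100.0])
        three, _ = gen_epsp_trace(onsets=(100.0, 500.0, 900.0),
                                  duration=1500.0, noise_sd=0.0)
        # well-separated events: integrate a window long enough for all
        _, int3 = summation_metrics(three, [100.0, 500.0, 900.0],
                                    integral_window=400.0)
        _, int1w = summation_metrics(one, [100.0], integral_window=1200.0)
        assert int3 == pytest.approx(3 * int1, rel=0.01)

    def test_matches_template_model_on_template_trace(self):
        from fsikir.template import TemplateParams, convolve_train
        p = TemplateParams()
        isi = 10.0
        tr = convolve_train(p, isi)
        amp, _ = summation_metrics(tr, [k * isi for k in range(5)])
        assert amp == pytest.approx(float(np.max(tr.samples)), abs=1e-9)

    def test_onsets_outside_trace_rejected(self):
        tr, _ = gen_epsp_trace()
        with pytest.raises(AnalysisError):
            summation_metrics(tr, [1e6])


class TestSpikes:
    def test_counts_suprathreshold_excursions(self):
        t = np.arange(0.0, 100.0, 0.05)
        v = np.full_like(t, -65.0)
        for ts in (20.0, 50.0, 80.0):
            v += 70.0 * np.exp(-((t - ts) ** 2) / (2 * 0.4**2))
        ev = detect_spikes(TraceRecord(dt=0.05, samples=v))
        assert len(ev) == 3
        assert np.allclose(ev.times, [20.0, 50.0, 80.0], atol=0.2)

    def test_subthreshold_trace_empty(self):
        tr, _ = gen_epsp_trace(noise_sd=0.0)
        assert len(detect_spikes(tr)) == 0

    def test_known_times_recovered(self):
        tr, truth = gen_spiking_trace(rate_hz=15.0, seed=2, noise_sd=0.1)
        ev = detect_spikes(tr)
        true_times = np.array(truth["spike_times"])
        assert len(ev) == len(true_times)
        assert np.max(np.abs(ev.times - true_times)) < 0.2

    def test_psth_uniform_rate(self):
        times = np.linspace(50.0, 950.0, 10)
        centers, rate = firing_rate_psth(EventSeries(times=times), 100.0,
                                         (0.0, 1000.0))
        assert np.allclose(rate, 10.0)

    def test_psth_conserves_counts(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 1000.0, 137))
        for bin_ms in (10.0, 50.0, 250.0):
            _, rate = firing_rate_psth(EventSeries(times=times), bin_ms,
                                       (0.0, 1000.0))
            assert int(round(np.sum(rate) * bin_ms / 1000.0)) == 137

    def test_psth_empty(self):
        _, rate = firing_rate_psth(EventSeries(times=np.array([])), 100.0,
                                   (0.0, 1000.0))
        assert np.all(rate == 0.0)


class TestSpikeFractionByIsi:
    def test_all_spikes_one_label(self):
        st_times = np.arange(0.0, 1000.0, 100.0)
        spikes = EventSeries(times=st_times + 5.0)
        out = spike_fraction_by_isi(spikes, st_times, [10] * st_times.size)
        assert out["percent"][10] == pytest.approx(100.0)
        assert out["unassigned"] == 0

    def test_no_spikes_flagged_empty(self):
        out = spike_fraction_by_isi(EventSeries(times=np.array([])),
                                    [0.0, 100.0], [5, 10])
        assert out["empty"]
        assert all(v == 0.0 for v in out["percent"].values())

    def test_known_probabilities_recovered_within_binomial_ci(self):
        rng = np.random.default_rng(5)
        labels = [5, 10, 20]
        probs = {5: 0.2, 10: 0.6, 20: 0.2}
        st_times, st_labels, spikes = [], [], []
        t = 0.0
        for _ in range(900):
            lab = labels[int(rng.integers(3))]
            t += 150.0
            st_times.append(t)
            st_labels.append(lab)
            if rng.random() < probs[lab]:
                spikes.append(t + rng.uniform(0.5, 9.0))
        out = spike_fraction_by_isi(EventSeries(times=np.sort(spikes)),
                                    st_times, st_labels)
        n = out["assigned"]
        # expected assigned fraction per label ∝ n_lab·p_lab
        counts = {lab: st_labels.count(lab) for lab in labels}
        total_exp = sum(counts[l] * probs[l] for l in labels)
        for lab in labels:
            p_exp = counts[lab] * probs[lab] / total_exp
            se = math.sqrt(p_exp * (1 - p_exp) / n)
            assert out["percent"][lab] / 100.0 == pytest.approx(
                p_exp, abs=2.5 * se)


class TestSubthresholdFromSpiking:
    def test_spike_free_trace_unchanged(self):
        tr, _ = gen_epsp_trace(amplitude=0.3, tau_rise=1.0, tau_decay=15.0,
                               noise_sd=0.0)
        filtered, _ = subthreshold_from_spiking(tr)
        assert np.max(np.abs(filtered.samples - tr.samples)) <= 0.05

    def test_dc_shift_recovered(self):
        """Spiking trace riding on a +1.19 mV depolarization: the filtered
        mean recovers the shifted level within 0.3 mV."""
        tr, truth = gen_spiking_trace(rate_hz=20.0, dc_shift=1.19,
                                      baseline=-65.0, seed=8)
        _, mean_v = subthreshold_from_spiking(tr)
        assert mean_v == pytest.approx(truth["dc_level"], abs=0.3)

    @pytest.mark.parametrize("rate", [5.0, 20.0, 50.0])
    def test_recovered_level_independent_of_rate(self, rate):
        tr, truth = gen_spiking_trace(rate_hz=rate, dc_shift=0.0,
                                      baseline=-65.0, seed=9)
        _, mean_v = subthreshold_from_spiking(tr)
        assert mean_v == pytest.approx(-65.0, abs=0.3)

    def test_mostly_spikes_rejected(self):
        tr, _ = gen_spiking_trace(rate_hz=400.0, refractory=1.0,
                                  duration=500.0, seed=10)
        with pytest.raises(AnalysisError):
            subthreshold_from_spiking(tr, excision_half_width=3.0)


class TestIeiBands:
    def test_high_gamma_at_15ms(self):
        ev = EventSeries(times=np.arange(0.0, 1500.0, 15.0))
        out = iei_band_probabilities(ev)
        assert out["probability"]["high_gamma"] == 1.0

    def test_low_gamma_at_25ms(self):
        ev = EventSeries(times=np.arange(0.0, 2500.0, 25.0))
        out = iei_band_probabilities(ev)
        assert out["probability"]["low_gamma"] == 1.0

    def test_band_edges_and_gap(self):
        bands = BandDefinition()
        assert bands.assign(1000.0 / 35.0) == "beta"  # 28.6 Hz
        assert bands.assign(1000.0 / 33.0) is None  # 30.3 Hz in the gap
        assert bands.assign(8.0) == "theta"  # lower band wins shared edge

    def test_probabilities_sum_to_one_exactly(self):
        rng = np.random.default_rng(11)
        ev = EventSeries(times=np.cumsum(rng.uniform(5.0, 300.0, 500)))
        out = iei_band_probabilities(ev)
        assert sum(out["probability"].values()) + out["unassigned"] == \
            pytest.approx(1.0, abs=1e-15)

    def test_needs_two_events(self):
        with pytest.raises(AnalysisError):
            iei_band_probabilities(EventSeries(times=np.array([1.0])))


class TestSpaceConstant:
    def test_noiseless_exponential_exact(self):
        d = np.linspace(0.0, 10.0, 16)
        y = 8.0 * np.exp(-d / 3.13)
        fit = fit_space_constant(d, y)
        assert fit.space_constant == pytest.approx(3.13, abs=1e-6)
        assert fit.decaying

    def test_constant_responses_flagged(self):
        fit = fit_space_constant(np.arange(5.0), np.ones(5))
        assert not fit.decaying
        assert math.isinf(fit.space_constant)

    def test_monte_carlo_recovery_with_noise(self):
        """20 % multiplicative noise, n=16: median recovered λ within 25 %
        of truth over 100 seeds."""
        from fsikir.synth import gen_distance_response
        lams = []
        for seed in range(100):
            d, y, _ = gen_distance_response(noise_cv=0.2, seed=seed)
            lams.append(fit_space_constant(d, y).space_constant)
        assert np.median(lams) == pytest.approx(3.13, rel=0.25)


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst_potential(10.0, 10.0) == 0.0

    def test_potassium_prediction(self):
        """aCSF 3 mM K⁺ out, 140 mM in (130 KGluconate + 10 KCl), 306 K →
        −101 mV rounded."""
        assert round(nernst_potential(3.0, 140.0, 306.0, 1)) == -101

    def test_antisymmetric(self):
        a = nernst_potential(3.0, 140.0)
        b = nernst_potential(140.0, 3.0)
        assert a == pytest.approx(-b, rel=1e-12)

    def test_invalid_concentration(self):
        with pytest.raises(AnalysisError):
            nernst_potential(0.0, 140.0)
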