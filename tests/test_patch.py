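"""Patch-clamp analyses: fits, event detection and waveform metrics."""

import numpy as np
import pytest

from neuroburst import synth
from neuroburst.patch import (
    SweepTrace,
    ap_metrics,
    boltzmann,
    capacitance_from_discharge,
    count_spikes,
    current_density,
    detect_epscs,
    detect_vc_bursts,
    find_rheobase,
    fit_boltzmann,
    fit_weighted_decay,
    na_inactivation_curves,
    percent_inhibition,
    sag_amplitude,
    subtract_a_current,
    weighted_tau,
)


def make_sweep(t, y, **kw):
    kw.setdefault("units", "pA")
    return SweepTrace(np.asarray(t, float), np.asarray(y, float), **kw)


class TestPassiveProperties:
    def test_capacitance_from_known_charge(self):
        # exponential transient of 0.2 pC (200 fC) on a 10 mV step -> 20 pF
        fs = 50000.0
        t = np.arange(0, 0.2, 1 / fs)
        y = np.zeros_like(t)
        tau = 0.001
        mask = (t >= 0.05) & (t < 0.15)
        y[mask] = (0.2 / tau) * np.exp(-(t[mask] - 0.05) / tau)
        sweep = make_sweep(t, y, step_on=0.05, step_off=0.15)
        assert capacitance_from_discharge(sweep, dV_mV=10.0) == pytest.approx(
            20.0, rel=0.01)

    def test_zero_transient_warns(self):
        t = np.arange(0, 0.2, 1e-4)
        sweep = make_sweep(t, np.zeros_like(t), step_on=0.05, step_off=0.15)
        with pytest.warns(UserWarning):
            assert capacitance_from_discharge(sweep, dV_mV=10.0) == 0.0

    def test_rc_forward_model_recovery(self):
        # series-R charging current: I = (dV/Rs) exp(-t/(Rs*C)); area = C*dV
        fs, C_pF, Rs_MOhm, dV = 100000.0, 25.0, 8.0, 10.0
        tau_s = Rs_MOhm * 1e6 * C_pF * 1e-12
        t = np.arange(0, 0.1, 1 / fs)
        y = np.zeros_like(t)
        mask = (t >= 0.02) & (t < 0.08)
        i0 = dV * 1e-3 / (Rs_MOhm * 1e6) * 1e12  # pA
        y[mask] = i0 * np.exp(-(t[mask] - 0.02) / tau_s)
        sweep = make_sweep(t, y, step_on=0.02, step_off=0.08)
        assert capacitance_from_discharge(sweep, dV_mV=dV) == pytest.approx(
            C_pF, rel=0.05)

    @pytest.mark.parametrize("peak,cap,expected", [
        (500.0, 25.0, 20.0), (0.0, 25.0, 0.0), (-800.0, 20.0, -40.0),
    ])
    def test_current_density(self, peak, cap, expected):
        assert current_density(peak, cap) == pytest.approx(expected)

    def test_current_density_requires_positive_capacitance(self):
        with pytest.raises(ValueError):
            current_density(100.0, 0.0)

    def test_density_scales_linearly(self):
        assert current_density(400.0, 25.0) == pytest.approx(
            2 * current_density(200.0, 25.0))


class TestBoltzmannFit:
    def test_noiseless_exact_recovery(self):
        v = np.linspace(-90, -30, 13)
        i = boltzmann(v, 1.0, -60.0, 6.0)
        fit = fit_boltzmann(v, i)
        assert fit.Imax == pytest.approx(1.0, abs=1e-6)
        assert fit.V50 == pytest.approx(-60.0, abs=1e-6)
        assert fit.km == pytest.approx(6.0, abs=1e-6)

    def test_half_maximum_at_v50(self):
        fit = fit_boltzmann(np.linspace(-100, -20, 15),
                            boltzmann(np.linspace(-100, -20, 15), 2.0, -55.0, -7.0))
        assert fit.predict(fit.V50) == pytest.approx(fit.Imax / 2)

    def test_fit_reduces_residual_vs_initial_guess(self):
        rng = np.random.default_rng(0)
        v = np.linspace(-120, -15, 15)
        i = boltzmann(v, 1.0, -65.0, -6.0) + rng.normal(0, 0.02, v.size)
        fit = fit_boltzmann(v, i)
        ss_fit = float(np.sum(fit.residuals ** 2))
        ss_guess = float(np.sum((i - boltzmann(v, i.max(), -60.0, -10.0)) ** 2))
        assert ss_fit < ss_guess

    def test_recovery_bias_small(self):
        v = np.linspace(-120, -15, 15)
        v50s = []
        for seed in range(100):
            _, i, _ = synth.gen_boltzmann_data(1.0, -65.0, -6.0, voltages=v,
                                               noise_sd=0.02, seed=seed)
            v50s.append(fit_boltzmann(v, i).V50)
        assert abs(np.mean(v50s) + 65.0) < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([-80, -60, -40], [0.9, 0.5, 0.1])


class TestInactivationCurves:
    @staticmethod
    def family(v50, km=-6.0, volts=None, shift=0.0):
        volts = np.arange(-120, 0, 10.0) if volts is None else volts
        fam = []
        for vp in volts:
            avail = boltzmann(vp, 1.0, v50, km)
            t = np.arange(0, 0.02, 2e-5)
            sig = -1500 * avail * np.exp(-t * 1e3 / 0.5) * (t < 0.005)
            fam.append((vp + shift,
                        make_sweep(t, sig, step_on=0.0, step_off=0.01)))
        return fam

    def test_known_v50_recovered(self):
        _, _, fit = na_inactivation_curves(self.family(-65.0), mode="fast")
        assert fit.V50 == pytest.approx(-65.0, abs=1.0)

    def test_most_hyperpolarized_normalises_to_one(self):
        _, norm, _ = na_inactivation_curves(self.family(-65.0), mode="slow")
        assert norm[0] == pytest.approx(1.0)

    def test_translation_equivariance(self):
        _, _, fit0 = na_inactivation_curves(self.family(-65.0))
        _, _, fit_shift = na_inactivation_curves(self.family(-65.0, shift=-10.0))
        assert fit_shift.V50 - fit0.V50 == pytest.approx(-10.0, abs=0.01)

    def test_missing_metadata_rejected(self):
        t = np.arange(0, 0.02, 2e-5)
        fam = [(None, make_sweep(t, -np.exp(-t * 200), step_on=0.0, step_off=0.01))]
        with pytest.raises(ValueError):
            na_inactivation_curves(fam)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            na_inactivation_curves(self.family(-65.0), mode="medium")


class TestWeightedDecay:
    def test_equal_areas_arithmetic(self):
        assert weighted_tau(1.0, 2.0, 1.0, 4.0) == pytest.approx(3.0)

    def test_biexponential_exact(self):
        t = np.arange(0, 40, 0.1)
        y = 0.5 * np.exp(-t / 2) + 0.5 * np.exp(-t / 4)
        fit = fit_weighted_decay(t, y)
        assert fit.model == "bi"
        assert fit.t_w == pytest.approx(3.0, rel=1e-3)

    def test_pure_mono_selected(self):
        t = np.arange(0, 40, 0.1)
        fit = fit_weighted_decay(t, 2.0 * np.exp(-t / 5.0))
        assert fit.model == "mono"
        assert fit.t_w == pytest.approx(fit.t1)
        assert fit.t1 == pytest.approx(5.0, rel=1e-3)

    def test_tw_between_components(self):
        t = np.arange(0, 60, 0.1)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 0.6 * np.exp(-t / 2) + 0.4 * np.exp(-t / 12)
            fit = fit_weighted_decay(t, y + rng.normal(0, 0.05, t.size))
            lo, hi = min(fit.t1, fit.t2), max(fit.t1, fit.t2)
            assert lo - 1e-9 <= fit.t_w <= hi + 1e-9

    def test_negative_going_events_supported(self):
        t = np.arange(0, 40, 0.1)
        fit = fit_weighted_decay(t, -20.0 * np.exp(-t / 6.0))
        assert fit.t1 == pytest.approx(6.0, rel=1e-3)
        assert fit.A1 < 0

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            fit_weighted_decay(np.arange(0, 3, 0.5), np.exp(-np.arange(0, 3, 0.5)))


class TestEPSCDetection:
    def test_flat_trace_no_events(self):
        t = np.arange(0, 20, 1e-4)
        assert detect_epscs(make_sweep(t, np.zeros_like(t)), noise_sd=1.0) == []

    def test_planted_events_recovered(self):
        sweep, truth = synth.gen_epsc_trace(rate_hz=50 / 60, amp_mean=8.0,
                                            amp_sd=0.5, noise_sd=1.0,
                                            duration_s=60.0, seed=1)
        events = detect_epscs(sweep, noise_sd=1.0)
        det = np.array([e.time_s for e in events])
        hits = sum(np.any(np.abs(det - t) < 0.01) for t in truth.event_times)
        assert hits >= 0.96 * len(truth.event_times)

    def test_slow_rise_events_rejected(self):
        # 20 ms linear rise is far above the 5 ms gate
        fs = 10000.0
        t = np.arange(0, 30, 1 / fs)
        y = np.zeros_like(t)
        for onset in np.arange(2, 28, 2.0):
            i0 = int(onset * fs)
            rise = np.linspace(0, -30, int(0.020 * fs))
            decay = -30 * np.exp(-np.arange(int(0.05 * fs)) / fs / 0.01)
            seg = np.concatenate([rise, decay])
            y[i0:i0 + seg.size] += seg
        assert detect_epscs(make_sweep(t, y), noise_sd=1.0) == []

    def test_short_epoch_warns(self):
        t = np.arange(0, 5, 1e-4)
        with pytest.warns(UserWarning):
            detect_epscs(make_sweep(t, np.zeros_like(t)), noise_sd=1.0)


class TestVCBursts:
    @staticmethod
    def rect_trace(amp=10.0, dur=3.0, fs=1000.0, total=60.0, polarity=-1):
        t = np.arange(0, total, 1 / fs)
        y = np.zeros_like(t)
        y[(t >= 10.0) & (t < 10.0 + dur)] = polarity * amp
        return make_sweep(t, y)

    def test_rectangular_burst_amplitude_and_charge(self):
        (b,) = detect_vc_bursts(self.rect_trace(10.0, 3.0))
        assert b.amplitude_pA == pytest.approx(10.0)
        assert b.charge_pC == pytest.approx(b.amplitude_pA * b.duration_s)
        assert b.duration_s == pytest.approx(3.0, abs=0.01)

    def test_short_deflection_rejected(self):
        assert detect_vc_bursts(self.rect_trace(10.0, 1.0)) == []

    def test_subthreshold_amplitude_rejected(self):
        assert detect_vc_bursts(self.rect_trace(6.0, 3.0)) == []

    def test_epsc_spikes_excluded_from_amplitude_not_charge(self):
        trace = self.rect_trace(12.0, 2.5, fs=1000.0)
        y = trace.signal.copy()
        spike_area = 0.0
        for onset in (10.5, 11.0, 11.5, 12.0):
            i0 = int(onset * 1000)
            y[i0:i0 + 2] += -100.0  # 2 ms, 100 pA fast events
            spike_area += 100.0 * 0.002
        spiked = make_sweep(trace.time_s, y)
        (b,) = detect_vc_bursts(spiked)
        assert b.amplitude_pA == pytest.approx(12.0, abs=0.5)
        base = 12.0 * b.duration_s
        assert b.charge_pC == pytest.approx(base + spike_area, rel=0.05)


class TestAPMetrics:
    def test_ground_truth_waveform_recovery(self):
        sweeps, truth = synth.gen_ap_sweeps(seed=0)
        m = ap_metrics(sweeps)
        p = truth.params
        assert m.threshold_mV == pytest.approx(p["threshold_mV"], abs=0.5)
        assert m.peak_mV == pytest.approx(p["peak_mV"], abs=0.1)
        assert m.amplitude_mV == pytest.approx(p["amplitude_mV"], abs=0.5)
        assert m.T50_ms == pytest.approx(p["T50_ms"], abs=0.1)
        assert m.rise_time_ms == pytest.approx(p["rise_time_ms"], abs=0.1)

    def test_zero_latency_sd_zero_jitter(self):
        sweeps, _ = synth.gen_ap_sweeps(currents=[60.0] * 5, latency_sd_ms=0.0,
                                        seed=1)
        m = ap_metrics(sweeps)
        assert m.jitter == pytest.approx(0.0, abs=1e-9)
        assert m.latency_ms == pytest.approx(10.0, abs=0.1)

    def test_jitter_is_cv_of_latency(self):
        sweeps = []
        for lat in (9.0, 10.0, 11.0):
            s, _ = synth.gen_ap_sweeps(currents=[60.0], latency_mean_ms=lat,
                                       latency_sd_ms=0.0, seed=2)
            sweeps.extend(s)
        m = ap_metrics(sweeps)
        # population SD(9,10,11)/mean = 0.8165/10
        assert m.jitter == pytest.approx(0.08165, abs=0.005)

    def test_translation_invariance(self):
        sweeps, _ = synth.gen_ap_sweeps(currents=[60.0], seed=3)
        m0 = ap_metrics(sweeps)
        shifted = [make_sweep(s.time_s, s.signal + 7.0, units="mV",
                              step_on=s.step_on, step_off=s.step_off)
                   for s in sweeps]
        m1 = ap_metrics(shifted)
        assert m1.threshold_mV - m0.threshold_mV == pytest.approx(7.0, abs=0.01)
        assert m1.peak_mV - m0.peak_mV == pytest.approx(7.0, abs=0.01)
        assert m1.amplitude_mV == pytest.approx(m0.amplitude_mV, abs=0.01)
        assert m1.T50_ms == pytest.approx(m0.T50_ms, abs=0.01)
        assert m1.area_mV_ms == pytest.approx(m0.area_mV_ms, rel=0.01)

    def test_no_spikes_returns_none(self):
        sweeps, _ = synth.gen_ap_sweeps(currents=[0.0, 10.0], seed=4)
        assert ap_metrics(sweeps) is None


class TestRheobase:
    def test_planted_threshold_recovered(self):
        stim = synth.make_ap_stimulator(43.0)
        assert find_rheobase(stim, coarse_step_pA=10.0) == pytest.approx(43.0)

    def test_threshold_below_first_coarse_step(self):
        stim = synth.make_ap_stimulator(7.0)
        assert find_rheobase(stim, coarse_step_pA=10.0) == pytest.approx(7.0)

    def test_non_spiking_cell_raises(self):
        stim = synth.make_ap_stimulator(10_000.0)
        with pytest.raises(RuntimeError):
            find_rheobase(stim, coarse_step_pA=50.0, max_pA=200.0)

    def test_subthreshold_sweeps_have_no_spikes(self):
        sweeps, _ = synth.gen_ap_sweeps(currents=[0.0, 20.0, 40.0], seed=5)
        assert all(count_spikes(s) == 0 for s in sweeps)


class TestKCurrentsAndSag:
    def test_identical_sweeps_zero_a_current(self):
        t = np.arange(0, 0.3, 1e-4)
        y = 100 * np.exp(-t / 0.05)
        a = make_sweep(t, y)
        wave, peak = subtract_a_current(a, make_sweep(t, y.copy()), 20.0)
        assert np.all(wave == 0) and peak == 0

    def test_planted_transient_density(self):
        t = np.arange(0, 0.3, 1e-4)
        transient = 600.0 * np.exp(-t * 1e3 / 20.0)
        hyper = make_sweep(t, 50.0 + transient)
        depol = make_sweep(t, 50.0 + np.zeros_like(t))
        _, peak = subtract_a_current(hyper, depol, capacitance_pF=20.0)
        assert peak == pytest.approx(30.0)

    def test_subtraction_antisymmetric(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 0.1, 1e-4)
        a = make_sweep(t, rng.normal(0, 5, t.size))
        b = make_sweep(t, rng.normal(0, 5, t.size))
        wave_ab, _ = subtract_a_current(a, b, 10.0)
        wave_ba, _ = subtract_a_current(b, a, 10.0)
        np.testing.assert_allclose(wave_ab, -wave_ba)

    def test_time_base_mismatch_rejected(self):
        a = make_sweep(np.arange(0, 0.1, 1e-4), np.zeros(1000))
        b = make_sweep(np.arange(0, 0.2, 2e-4), np.zeros(1000))
        with pytest.raises(ValueError):
            subtract_a_current(a, b, 10.0)

    @pytest.mark.parametrize("control,drug,expected", [
        (100.0, 85.0, 15.0), (50.0, 50.0, 0.0), (200.0, 0.0, 100.0),
    ])
    def test_percent_inhibition(self, control, drug, expected):
        assert percent_inhibition(control, drug) == pytest.approx(expected)

    def test_percent_inhibition_zero_control(self):
        with pytest.raises(ValueError):
            percent_inhibition(0.0, 10.0)

    def test_monotone_relaxation_no_sag(self):
        t = np.arange(0, 1.0, 1e-3)
        v = np.full_like(t, -65.0)
        mask = (t >= 0.2) & (t < 0.8)
        v[mask] = -65 - 20 * (1 - np.exp(-(t[mask] - 0.2) / 0.03))
        sweep = make_sweep(t, v, units="mV", step_on=0.2, step_off=0.8)
        assert sag_amplitude(sweep) == pytest.approx(0.0, abs=0.1)

    def test_constructed_rebound_measured(self):
        t = np.arange(0, 1.0, 1e-3)
        v = np.full_like(t, -65.0)
        v[(t >= 0.2) & (t < 0.5)] = -88.0   # trough plateau
        v[(t >= 0.5) & (t < 0.8)] = -80.0   # relaxed steady state
        sweep = make_sweep(t, v, units="mV", step_on=0.2, step_off=0.8)
        assert sag_amplitude(sweep) == pytest.approx(8.0, abs=0.01)

    def test_sag_grows_with_step_size(self):
        sags = []
        for scale in (1.0, 2.0, 3.0):
            t = np.arange(0, 1.0, 1e-3)
            v = np.full_like(t, -65.0)
            mask = (t >= 0.2) & (t < 0.8)
            tt = (t[mask] - 0.2) * 1e3
            v[mask] = (-65 - scale * 15 * (1 - np.exp(-tt / 20))
                       + scale * 4 * (1 - np.exp(-tt / 80)))
            sags.append(sag_amplitude(
                make_sweep(t, v, units="mV", step_on=0.2, step_off=0.8)))
        assert sags[0] < sags[1] < sags[2]


class TestSweepValidation:
    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.15, 0.4])
        with pytest.raises(ValueError):
            SweepTrace(t, np.zeros(4))

    def test_step_window_must_fit(self):
        t = np.arange(0, 0.1, 1e-3)
        with pytest.raises(ValueError):
            SweepTrace(t, np.zeros_like(t), step_on=0.05, step_off=0.5)
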