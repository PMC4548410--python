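"""Connection detector: averaging, criteria, latency, rise, reversal."""

import numpy as np
import pytest

from sacphys import (
    PSCParams,
    StimulusProtocol,
    average_sweeps,
    detect_connection,
    ei_onset_difference,
    estimate_reversal,
    measure_latency,
    measure_rise_time,
    peak_amplitude,
    peak_ratio,
    simulate_paired_recording,
    simulate_psc_waveform,
    trial_presence_fraction,
)
from sacphys.connections import FitError

from conftest import make_sweepset

RATE = 20_000.0
DT = 1000.0 / RATE


def boltzmann_trace(t_half_ms=68.0, k_ms=0.5, amp=15.0, n=6000):
    t = np.arange(n) * DT
    return amp / (1.0 + np.exp((t_half_ms - t) / k_ms))


class TestAverageSweeps:
    def test_identical_trials_average_to_one_trial(self, rng):
        trial = rng.normal(0, 1, 6000)
        sweeps = make_sweepset(np.tile(trial, (10, 1)))
        mean, _, _ = average_sweeps(sweeps)
        assert np.allclose(mean, trial)

    def test_baseline_sd_shrinks_with_sqrt_n(self):
        # CLT oracle: averaged-baseline SD ~ sigma / sqrt(n_trials)
        sds = {}
        for n in (4, 64):
            reps = []
            for s in range(40):
                traces = np.random.default_rng(1000 * n + s).normal(0, 2, (n, 6000))
                reps.append(average_sweeps(make_sweepset(traces))[2])
            sds[n] = np.mean(reps)
        assert sds[4] / sds[64] == pytest.approx(4.0, rel=0.2)

    def test_short_baseline_rejected(self):
        protocol = StimulusProtocol(30.0, 200.0, -70.0, 20.0, 30.0)
        sweeps = make_sweepset(np.zeros((2, 6000)), protocol=protocol)
        with pytest.raises(ValueError, match="baseline"):
            average_sweeps(sweeps)


class TestLatency:
    def test_boltzmann_closed_form(self):
        # tangent of max slope meets baseline at t_half - 2k
        trace = boltzmann_trace(t_half_ms=68.0, k_ms=0.5)
        trace += np.random.default_rng(0).normal(0, 1e-4, trace.size)
        lat = measure_latency(trace, RATE, 60.0)
        assert lat == pytest.approx(8.0 - 2 * 0.5, abs=0.01)

    def test_step_rise_limit(self):
        # k -> 0: latency -> step time - onset
        trace = np.zeros(6000)
        trace[1360:] = 15.0  # step at 68 ms
        trace += np.random.default_rng(1).normal(0, 1e-4, 6000)
        lat = measure_latency(trace, RATE, 60.0)
        assert lat == pytest.approx(8.0, abs=0.1)

    def test_planted_psc_recovery_within_half_ms(self):
        psc = PSCParams(failure_prob=0.0)
        w = simulate_psc_waveform(psc, 60.0, RATE, 300.0)
        errs = []
        for s in range(100):
            noise = np.random.default_rng(s).normal(0, 15.0 / 5 / np.sqrt(10), w.size)
            errs.append(measure_latency(w + noise, RATE, 60.0) - 7.0)
        assert np.max(np.abs(errs)) < 0.5

    def test_undetectable_peak_raises(self, rng):
        # noisy baseline but a post-onset deflection under 2 baseline SD
        trace = rng.normal(0, 1, 6000)
        trace[1200:] = 1.0
        with pytest.raises(FitError, match="2 baseline SD"):
            measure_latency(trace, RATE, 60.0)


class TestRiseTime:
    def test_linear_ramp(self):
        trace = np.zeros(6000)
        ramp = np.linspace(0, 15, int(5 / DT), endpoint=False)
        trace[1220 : 1220 + ramp.size] = ramp
        trace[1220 + ramp.size :] = 15.0
        assert measure_rise_time(trace, RATE, 60.0) == pytest.approx(4.0, abs=0.1)

    def test_difference_of_exponentials_against_dense_oracle(self):
        # dense-grid evaluation of the tau_r=1, tau_d=20 waveform: 1.5710 ms
        w = simulate_psc_waveform(PSCParams(), 60.0, RATE, 300.0)
        assert measure_rise_time(w, RATE, 60.0) == pytest.approx(1.5710, abs=0.06)

    def test_instantaneous_step_within_one_sample(self):
        trace = np.zeros(6000)
        trace[1400:] = 10.0
        assert measure_rise_time(trace, RATE, 60.0) <= DT


class TestPresenceFraction:
    def test_all_trials_high_snr(self):
        rec = simulate_paired_recording(True, psc=PSCParams(failure_prob=0), seed=0)
        assert trial_presence_fraction(rec.sweeps, polarity=1) == 1.0

    def test_planted_six_of_ten(self):
        rec = simulate_paired_recording(
            True, present_mask=[True] * 6 + [False] * 4, seed=1
        )
        assert trial_presence_fraction(rec.sweeps, polarity=1) == pytest.approx(0.6)

    def test_pure_noise_rarely_present(self):
        fracs = [
            trial_presence_fraction(
                simulate_paired_recording(False, seed=s).sweeps, polarity=1
            )
            for s in range(40)
        ]
        assert np.mean([f <= 0.2 for f in fracs]) >= 0.95

    def test_zero_variance_baseline_rejected(self):
        sweeps = make_sweepset(np.zeros((3, 6000)))
        with pytest.raises(ValueError, match="zero-variance"):
            trial_presence_fraction(sweeps, polarity=1)


class TestDetectConnection:
    def test_compliant_planted_psc_detected(self):
        rec = simulate_paired_recording(True, psc=PSCParams(failure_prob=0), seed=0)
        res = detect_connection(rec)
        assert res.verdict
        assert res.latency_ms == pytest.approx(7.0, abs=0.5)
        assert res.rise_10_90_ms < 4.0
        assert res.peak_pA > 10.0

    def test_flat_noiseless_fails_peak_criterion(self):
        rec = simulate_paired_recording(False, noise_sd_pA=0.0, seed=0)
        res = detect_connection(rec)
        assert not res.verdict
        assert not res.criteria["peak"]

    def test_long_latency_fails_only_kinetics(self):
        psc = PSCParams(latency_ms=13.0, failure_prob=0.0)
        res = detect_connection(simulate_paired_recording(True, psc=psc, seed=2))
        assert not res.verdict
        assert res.criteria["peak"] and res.criteria["presence"]
        assert not res.criteria["kinetics"]
        assert res.latency_ms > 12.0

    def test_slow_rise_fails_only_kinetics(self):
        # tau_rise 4 ms gives a 10-90 rise of ~4.4 ms (dense-grid oracle)
        psc = PSCParams(tau_rise_ms=4.0, failure_prob=0.0)
        res = detect_connection(simulate_paired_recording(True, psc=psc, seed=3))
        assert not res.verdict
        assert res.criteria["peak"] and res.criteria["presence"]
        assert not res.criteria["kinetics"]
        assert res.rise_10_90_ms > 4.0

    def test_seven_of_ten_presence_fails_only_presence(self):
        rec = simulate_paired_recording(
            True,
            psc=PSCParams(failure_prob=0.0),
            present_mask=[True] * 7 + [False] * 3,
            seed=4,
        )
        res = detect_connection(rec)
        assert not res.verdict
        assert res.criteria["peak"] and res.criteria["kinetics"]
        assert not res.criteria["presence"]
        assert res.trial_fraction == pytest.approx(0.7)

    def test_subthreshold_peak_fails_peak_criterion(self):
        # a deflection this small also cannot sustain per-trial excursions,
        # so presence fails with it; the peak criterion is the one probed
        rec = simulate_paired_recording(
            True, psc=PSCParams(amplitude_pA=0.5, amp_cv=0, failure_prob=0),
            noise_sd_pA=2.0, seed=5,
        )
        res = detect_connection(rec)
        assert not res.verdict

    def test_monotonicity_in_amplitude(self):
        # fixed noise seed: raising planted amplitude never flips true->false
        verdicts = []
        for amp in (5.0, 10.0, 20.0, 40.0):
            rec = simulate_paired_recording(
                True, psc=PSCParams(amplitude_pA=amp, amp_cv=0, failure_prob=0), seed=11
            )
            verdicts.append(detect_connection(rec).verdict)
        assert verdicts == sorted(verdicts)

    def test_offset_invariance(self):
        rec = simulate_paired_recording(True, psc=PSCParams(failure_prob=0), seed=6)
        base = detect_connection(rec)
        rec.sweeps.traces = rec.sweeps.traces + 40.0
        shifted = detect_connection(rec)
        assert shifted.verdict == base.verdict
        assert shifted.latency_ms == pytest.approx(base.latency_ms, abs=1e-6)
        assert shifted.rise_10_90_ms == pytest.approx(base.rise_10_90_ms, abs=1e-6)


class TestPeakAmplitude:
    def test_noiseless_waveform_read_exactly(self):
        w = simulate_psc_waveform(PSCParams(), 60.0, RATE, 300.0)
        assert peak_amplitude(w, RATE, 60.0) == pytest.approx(15.0, rel=0.01)

    def test_smoothing_removes_noise_crest_bias(self):
        # raw max over the window rides the noise crest; the smoothed
        # readout must land within ~2 % of the planted mean
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(100):
            rec = simulate_paired_recording(
                True, psc=PSCParams(failure_prob=0.0), seed=rng
            )
            vals.append(
                peak_amplitude(rec.sweeps.traces.mean(axis=0), RATE, 60.0)
            )
        assert np.mean(vals) == pytest.approx(15.0, rel=0.03)

    def test_sign_follows_polarity(self):
        w = -simulate_psc_waveform(PSCParams(), 60.0, RATE, 300.0)
        assert peak_amplitude(w, RATE, 60.0) == pytest.approx(-15.0, rel=0.01)


class TestReversal:
    def test_linear_iv_reverses_at_minus_70(self):
        v = np.arange(-70, 31, 20.0)
        iv = estimate_reversal(v, 0.2 * (v + 70))
        assert iv.reversal_mV == pytest.approx(-70.0)
        assert not iv.extrapolated

    def test_all_zero_currents_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_reversal([-70, -50, -30], [0, 0, 0])

    def test_same_sign_currents_extrapolated_with_warning(self):
        v = np.array([-30.0, -10.0, 10.0, 30.0])
        with pytest.warns(UserWarning, match="extrapolated"):
            iv = estimate_reversal(v, 0.2 * (v + 70))
        assert iv.extrapolated
        assert iv.reversal_mV == pytest.approx(-70.0, abs=1e-6)

    def test_noisy_iv_tracks_regression_oracle(self):
        # regression oracle: the least-squares line's zero crossing is an
        # unbiased estimate of the reversal; the interpolation estimator
        # must agree with it on average (its crossing-selection bias is a
        # small fraction of the spread)
        v = np.arange(-70, 31, 20.0)
        revs, oracle = [], []
        for s in range(100):
            i = 0.2 * (v + 70) + np.random.default_rng(s).normal(0, 0.5, v.size)
            revs.append(estimate_reversal(v, i).reversal_mV)
            slope, intercept = np.polyfit(v, i, 1)
            oracle.append(-intercept / slope)
        se = np.std(oracle) / 10
        assert abs(np.mean(oracle) + 70.0) < 3 * se
        assert abs(np.mean(revs) - np.mean(oracle)) < 1.0


class TestTraceComparisons:
    def test_ei_identical_traces_zero_difference(self):
        w = simulate_psc_waveform(PSCParams(), 60.0, RATE, 300.0)
        w = w + np.random.default_rng(0).normal(0, 0.1, w.size)
        assert ei_onset_difference(w, w, RATE, 60.0) == pytest.approx(0.0, abs=1e-9)

    def test_ei_planted_fifty_ms_lag(self):
        rng = np.random.default_rng(1)
        exc = -simulate_psc_waveform(PSCParams(), 60.0, RATE, 400.0)
        inh = simulate_psc_waveform(PSCParams(latency_ms=57.0), 60.0, RATE, 400.0)
        exc = exc + rng.normal(0, 0.2, exc.size)
        inh = inh + rng.normal(0, 0.2, inh.size)
        delta = ei_onset_difference(exc, inh, RATE, 60.0, search_window_ms=80.0)
        assert delta == pytest.approx(50.0, abs=1.0)
        # antisymmetry
        assert ei_onset_difference(
            inh, exc, RATE, 60.0, search_window_ms=80.0
        ) == pytest.approx(-delta, abs=1e-9)

    def test_peak_ratio_homogeneity(self):
        rng = np.random.default_rng(2)
        w = simulate_psc_waveform(PSCParams(), 60.0, RATE, 300.0)
        a = w + rng.normal(0, 0.01, w.size)
        assert peak_ratio(a, a, RATE, 60.0) == pytest.approx(1.0)
        assert peak_ratio(2 * a, a, RATE, 60.0) == pytest.approx(2.0, rel=1e-6)

    def test_peak_ratio_planted_half(self):
        ratios = []
        for s in range(100):
            rng = np.random.default_rng(s)
            a = simulate_psc_waveform(PSCParams(amplitude_pA=15), 60.0, RATE, 300.0)
            b = simulate_psc_waveform(PSCParams(amplitude_pA=30), 60.0, RATE, 300.0)
            ratios.append(
                peak_ratio(
                    a + rng.normal(0, 0.6, a.size),
                    b + rng.normal(0, 0.6, b.size),
                    RATE,
                    60.0,
                )
            )
        assert np.mean(ratios) == pytest.approx(0.5, rel=0.1)

    def test_zero_denominator_rejected(self):
        w = simulate_psc_waveform(PSCParams(), 60.0, RATE, 300.0)
        with pytest.raises(ZeroDivisionError):
            peak_ratio(w, np.zeros_like(w), RATE, 60.0)
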