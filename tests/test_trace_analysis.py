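import math

import numpy as np
import pytest

from ornpulse import synthetic, trace_analysis as ta
from ornpulse.imaging_io import FluorescenceTrace


def make_trace(values, rate=20.0):
    return FluorescenceTrace(np.asarray(values, dtype=float), rate)


class TestComputeDff:
    def test_constant_trace_zero(self):
        dff = ta.compute_dff(make_trace([5.0] * 10), "prior")
        assert dff.f0 == pytest.approx(5.0)
        assert np.allclose(dff.values, 0.0)

    def test_lowest_quartile_convention(self):
        dff = ta.compute_dff(make_trace([1, 2, 3, 4, 5, 6, 7, 8]), "prior")
        assert dff.f0 == pytest.approx(1.5)  # mean of the lowest 2 of 8
        assert dff.values[2] == pytest.approx((3 - 1.5) / 1.5)  # = 1.0 at F = 3

    def test_stim_mode_nine_frames(self):
        F = [10.0] * 9 + [15.0, 12.0]
        protocol = ta.StimulusProtocol("pulse", [0.0], [1.0])
        dff = ta.compute_dff(make_trace(F, rate=9.0), "stim", protocol)
        assert dff.f0 == pytest.approx(10.0)
        assert dff.values[9] == pytest.approx(0.5)

    def test_stim_mode_needs_nine_frames(self):
        protocol = ta.StimulusProtocol("pulse", [0.0], [0.5])
        with pytest.raises(ValueError, match="9 frames"):
            ta.compute_dff(make_trace([10.0] * 5), "stim", protocol)

    def test_scale_invariance(self):
        tr = make_trace([3, 1, 4, 1, 5, 9, 2, 6])
        scaled = make_trace(7.0 * tr.values)
        assert np.allclose(
            ta.compute_dff(tr, "prior").values, ta.compute_dff(scaled, "prior").values
        )

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            ta.compute_dff(make_trace([-5.0, -4.0, 1.0, 2.0]), "prior")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ta.compute_dff(make_trace([1.0, 2.0]), "prior")


class TestDetectEvents:
    def test_constant_trace_zero_events(self):
        dff = ta.DFFTrace(np.zeros(100), 1.0, "prior_percentile", 20.0)
        ev = ta.detect_events(dff)
        assert ev.n_events == 0
        assert ev.sigma == 0.0

    def test_single_spike(self):
        # zeros + one sample of 10: median 0, sigma 3 < 10/2 -> one event
        x = np.zeros(10)
        x[4] = 10.0
        ev = ta.detect_events(ta.DFFTrace(x, 1.0, "prior_percentile", 1.0))
        assert ev.n_events == 1
        assert ev.event_times[0] == pytest.approx(4.0)
        assert ev.event_amplitudes[0] == pytest.approx(10.0)

    def test_run_counted_once(self):
        x = np.zeros(50)
        x[10:14] = [5.0, 8.0, 9.0, 4.0]  # one excursion
        ev = ta.detect_events(ta.DFFTrace(x, 1.0, "prior_percentile", 1.0))
        assert ev.n_events == 1
        assert ev.event_amplitudes[0] == pytest.approx(9.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        x[50] = 25.0
        a = ta.detect_events(ta.DFFTrace(x, 1.0, "prior_percentile", 20.0))
        b = ta.detect_events(ta.DFFTrace(x + 3.0, 1.0, "prior_percentile", 20.0))
        assert a.n_events == b.n_events
        assert np.allclose(a.event_times, b.event_times)

    def test_recovers_ground_truth_count(self):
        params = synthetic.recovery_params(0.5, seed=42)
        trace, gt = synthetic.simulate_calcium_trace(params)
        dff = ta.compute_dff(trace, "prior")
        ev = ta.detect_events(dff)
        assert ev.n_events == pytest.approx(gt.n_events, rel=0.2)

    def test_min_duration_knob(self):
        x = np.zeros(50)
        x[10] = 10.0
        dff = ta.DFFTrace(x, 1.0, "prior_percentile", 10.0)
        assert ta.detect_events(dff).n_events == 1
        assert ta.detect_events(dff, min_duration=0.5).n_events == 0


class TestFrequency:
    def test_arithmetic(self):
        ev = ta.EventSet(np.linspace(0, 9, 9), np.ones(9), 0.1, 0.0)
        assert ta.event_frequency(ev, 10.0) == pytest.approx(0.9)

    def test_zero_events(self):
        ev = ta.EventSet(np.array([]), np.array([]), 0.1, 0.0)
        assert ta.event_frequency(ev, 10.0) == 0.0

    def test_zero_duration_rejected(self):
        ev = ta.EventSet(np.array([]), np.array([]), 0.1, 0.0)
        with pytest.raises(ValueError):
            ta.event_frequency(ev, 0.0)


class TestPowerSpectrum:
    def test_sinusoid_peak_at_its_frequency(self):
        t = np.arange(1200) / 20.0
        x = np.sin(2 * np.pi * 0.5 * t)
        sp = ta.power_spectrum(ta.DFFTrace(x, 1.0, "prior_percentile", 20.0))
        assert sp.frequencies[np.argmax(sp.power)] == pytest.approx(0.5)

    def test_constant_trace_all_zero_power(self):
        sp = ta.power_spectrum(ta.DFFTrace(np.full(100, 2.0), 1.0, "prior_percentile", 20.0))
        assert np.allclose(sp.power, 0.0)

    def test_parseval(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=999)
        dff = ta.DFFTrace(x, 1.0, "prior_percentile", 20.0)
        sp = ta.power_spectrum(dff)
        df = sp.frequencies[1] - sp.frequencies[0]
        assert np.sum(sp.power) * df == pytest.approx(np.var(x), rel=1e-6)

    def test_average_spectra_sem(self):
        dffs = [
            ta.DFFTrace(np.sin(np.arange(100) * f), 1.0, "prior_percentile", 20.0)
            for f in (0.3, 0.3)
        ]
        spectra = [ta.power_spectrum(d) for d in dffs]
        _, mean, sem = ta.average_spectra(spectra)
        assert np.allclose(sem, 0.0)
        assert np.allclose(mean, spectra[0].power)

    def test_mixed_rates_rejected(self):
        a = ta.power_spectrum(ta.DFFTrace(np.zeros(100), 1.0, "prior_percentile", 20.0))
        b = ta.power_spectrum(ta.DFFTrace(np.zeros(100), 1.0, "prior_percentile", 10.0))
        with pytest.raises(ValueError):
            ta.average_spectra([a, b])

    def test_averaged_white_noise_is_flat(self):
        # single-trace periodograms are exponential-distributed and DO
        # exceed 5x the median regularly; the flatness statement holds
        # for the cross-trace average (20 traces per run)
        flat_runs = 0
        n_runs = 30
        for run in range(n_runs):
            specs = []
            for k in range(20):
                rng = np.random.default_rng(1000 * run + k)
                x = rng.normal(size=1200)
                specs.append(
                    ta.power_spectrum(ta.DFFTrace(x, 1.0, "prior_percentile", 20.0))
                )
            _, mean, _ = ta.average_spectra(specs)
            mean = mean[1:]  # DC bin is zeroed by mean subtraction
            if mean.max() <= 5.0 * np.median(mean):
                flat_runs += 1
        assert flat_runs >= 0.95 * n_runs

    def test_rhythmic_generator_shows_spectral_peak(self):
        f0 = 0.5

        def mean_spectrum(modulated):
            specs = []
            for s in range(30):
                kwargs = {"rate_mod_freq": f0, "rate_mod_depth": 0.9} if modulated else {}
                params = synthetic.recovery_params(0.9, seed=500 + s, **kwargs)
                tr, _ = synthetic.simulate_calcium_trace(params)
                specs.append(ta.power_spectrum(ta.compute_dff(tr, "prior")))
            freqs, mean, _ = ta.average_spectra(specs)
            return freqs, mean

        freqs, m_mod = mean_spectrum(True)
        _, m_flat = mean_spectrum(False)
        i0 = np.argmin(np.abs(freqs - f0))
        band = (np.abs(freqs - f0) > 0.15) & (freqs > 0.1) & (freqs < 1.5)
        assert m_mod[i0] / np.median(m_mod[band]) > 3.0
        assert m_flat[i0] / np.median(m_flat[band]) < 2.0


class TestResponseMetrics:
    protocol = ta.StimulusProtocol("continuous", [5.0], [18.0])

    def _dff_from_sim(self, params):
        tr = synthetic.simulate_stim_response_trace(params)
        # normalize with the known true baseline for closed-form checks
        return ta.DFFTrace(
            (tr.values - params.baseline_level) / params.baseline_level,
            params.baseline_level,
            "stim_onset_frames",
            params.sample_rate,
        )

    def test_adapting_mode_closed_form(self):
        params = synthetic.StimSimParams(
            protocol=self.protocol,
            onset_gain=1.0,
            adaptation_tau=6.0,
            undershoot_depth=0.0,
            noise_sigma=0.0,
            duration=40.0,
        )
        dff = self._dff_from_sim(params)
        m = ta.response_metrics(dff, self.protocol, post_window=10.0)
        assert m.dff_max == pytest.approx(1.0)
        i_off = round(23.0 * params.sample_rate)
        assert dff.values[i_off] == pytest.approx(math.exp(-18.0 / 6.0), rel=1e-9)
        assert m.undershoot >= 0.0  # never drops below baseline
        assert m.return_time is None or m.return_time > 1.0

    def test_sustained_mode_undershoot(self):
        params = synthetic.StimSimParams(
            protocol=self.protocol,
            onset_gain=1.0,
            adaptation_tau=None,
            undershoot_depth=0.1,
            noise_sigma=0.0,
            duration=40.0,
        )
        dff = self._dff_from_sim(params)
        m = ta.response_metrics(dff, self.protocol, post_window=10.0)
        assert m.undershoot == pytest.approx(-0.1)
        assert m.return_time is not None
        assert m.return_time <= 1.0 / params.sample_rate

    def test_zero_gain(self):
        params = synthetic.StimSimParams(
            protocol=self.protocol, onset_gain=0.0, noise_sigma=0.0, duration=40.0
        )
        dff = self._dff_from_sim(params)
        m = ta.response_metrics(dff, self.protocol)
        assert m.dff_max == pytest.approx(0.0, abs=1e-12)
        assert m.return_time == pytest.approx(0.0)

    def test_post_window_truncation_warns(self):
        params = synthetic.StimSimParams(
            protocol=self.protocol, onset_gain=1.0, noise_sigma=0.0, duration=25.0
        )
        dff = self._dff_from_sim(params)
        with pytest.warns(UserWarning, match="truncated"):
            ta.response_metrics(dff, self.protocol, post_window=60.0)


class TestPriorToEvokedRatio:
    def test_single_event(self):
        ev = ta.EventSet([1.0], [0.3], 0.05, 0.0)
        assert ta.prior_to_evoked_ratio(ev, 0.6) == pytest.approx(50.0)

    def test_mean_of_amplitudes(self):
        ev = ta.EventSet([1.0, 2.0], [0.2, 0.4], 0.05, 0.0)
        assert ta.prior_to_evoked_ratio(ev, 0.6) == pytest.approx(50.0)

    def test_no_events_undefined(self):
        ev = ta.EventSet([], [], 0.05, 0.0)
        with pytest.warns(UserWarning):
            assert math.isnan(ta.prior_to_evoked_ratio(ev, 0.6))

    def test_calibrated_generator_near_target(self):
        ratios = []
        for s in range(30):
            params = synthetic.recovery_params(0.9, seed=7000 + s)
            tr, _ = synthetic.simulate_calcium_trace(params)
            ev = ta.detect_events(ta.compute_dff(tr, "prior"))
            if ev.n_events:
                ratios.append(ta.prior_to_evoked_ratio(ev, synthetic.DEFAULT_EVOKED_DFF_MAX))
        assert abs(np.mean(ratios) - 61.1) < 10.0


class TestAverageTraces:
    def _dff(self, values):
        return ta.DFFTrace(np.asarray(values, dtype=float), 1.0, "prior_percentile", 20.0)

    def test_identical_traces(self):
        a = self._dff([1.0, 2.0, 3.0])
        mean, sem = ta.average_traces([a, a])
        assert np.allclose(mean, a.values)
        assert np.allclose(sem, 0.0)

    def test_plus_minus_one(self):
        mean, sem = ta.average_traces([self._dff([1.0] * 5), self._dff([-1.0] * 5)])
        assert np.allclose(mean, 0.0)
        assert np.allclose(sem, 1.0)  # sd = sqrt(2), / sqrt(2) = 1

    def test_single_trace_sem_unavailable(self):
        mean, sem = ta.average_traces([self._dff([1.0, 2.0])])
        assert np.allclose(mean, [1.0, 2.0])
        assert np.all(np.isnan(sem))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ta.average_traces([self._dff([1.0, 2.0]), self._dff([1.0, 2.0, 3.0])])
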