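from __future__ import annotations

import numpy as np
import pytest

from conftest import match_signatures_to_truth
from dropletpix.peak_detection import (
    DetectorConfig,
    Peak,
    PeakDetector,
    detect_peaks,
    detector_score,
    group_peaks,
)
from dropletpix.synthetic_data import (
    GroupSpec,
    PopulationSpec,
    Pulse,
    TraceSpec,
    make_population_traces,
    make_trace,
)
from dropletpix.trace import Trace


def single_droplet_trace(noise_sd=0.01, seed=5):
    """One droplet: three pulses of height 10*noise_sd over a noisy baseline."""
    h = 10 * noise_sd
    return make_trace(
        TraceSpec(
            sample_rate=10_000.0,
            duration=0.1,
            baseline_level=0.1,
            noise_sd=noise_sd,
            pulses=tuple(Pulse(0.05 + i * 0.003, h, 3e-4) for i in range(3)),
            seed=seed,
        )
    )


class TestDetectPeaks:
    def test_flat_noisy_trace_no_peaks(self):
        trace = make_trace(
            TraceSpec(sample_rate=10_000.0, duration=0.5, baseline_level=0.1,
                      noise_sd=0.02, seed=1)
        )
        cfg = DetectorConfig(baseline_window=100, threshold_multiple=5.0)
        assert detect_peaks(trace, cfg) == []

    def test_three_pulse_droplet_three_peaks(self):
        trace = single_droplet_trace()
        cfg = DetectorConfig(baseline_window=100)
        peaks = detect_peaks(trace, cfg)
        assert len(peaks) == 3

    def test_magnitude_measured_from_entry_baseline(self):
        # near-noise-free: magnitude equals the pulse height to within noise
        trace = make_trace(
            TraceSpec(sample_rate=50_000.0, duration=0.05, baseline_level=0.2,
                      noise_sd=1e-4, pulses=(Pulse(0.025, 1.0, 5e-4),), seed=2)
        )
        cfg = DetectorConfig(baseline_window=100, min_peak_samples=2)
        peaks = detect_peaks(trace, cfg)
        assert len(peaks) == 1
        assert peaks[0].magnitude == pytest.approx(1.0, rel=2e-3)
        assert peaks[0].baseline_at_entry == pytest.approx(0.2, abs=1e-3)

    def test_trace_shorter_than_window_errors(self):
        trace = make_trace(TraceSpec(sample_rate=100.0, duration=0.5))
        with pytest.raises(ValueError, match="warm"):
            detect_peaks(trace, DetectorConfig(baseline_window=100))

    def test_non_uniform_sampling_errors(self):
        t = np.concatenate([np.linspace(0, 1, 500), np.linspace(1.1, 3, 500)])
        trace = Trace(t, np.zeros(1000))
        with pytest.raises(ValueError, match="uniform"):
            detect_peaks(trace, DetectorConfig(baseline_window=100))

    def test_min_peak_samples_discards_spikes(self):
        # one-sample glitch on an otherwise flat trace
        signal = np.full(2000, 0.1) + np.random.default_rng(0).normal(0, 0.005, 2000)
        signal[1000] += 1.0
        trace = Trace(np.arange(2000) / 1e4, signal)
        cfg_keep = DetectorConfig(baseline_window=100, min_peak_samples=1)
        cfg_drop = DetectorConfig(baseline_window=100, min_peak_samples=3)
        assert len(detect_peaks(trace, cfg_keep)) == 1
        assert len(detect_peaks(trace, cfg_drop)) == 0

    @pytest.mark.parametrize("n_pulses", [5, 20])
    def test_peak_conservation_at_high_snr(self, n_pulses):
        # pulse spacing (200 samples) comfortably exceeds the baseline window
        # (100 samples) so each pulse arrives over a shoulder-free window
        noise_sd = 0.01
        spec = TraceSpec(
            sample_rate=10_000.0,
            duration=0.05 + 0.02 * n_pulses,
            baseline_level=0.1,
            noise_sd=noise_sd,
            pulses=tuple(
                Pulse(0.03 + i * 0.02, 10 * noise_sd, 5e-4) for i in range(n_pulses)
            ),
            seed=9,
        )
        # debounce suppresses splits where noise briefly dips a crossing
        # below threshold mid-pulse
        cfg = DetectorConfig(baseline_window=100, min_peak_samples=3,
                             min_below_to_close=3)
        peaks = detect_peaks(make_trace(spec), cfg)
        assert len(peaks) == n_pulses

    def test_threshold_monotonicity(self):
        trace = make_population_traces(
            PopulationSpec(
                groups=(GroupSpec((0.3, 0.3, 0.3), cv=0.05),),
                droplets_per_group=30,
                transit_spacing=0.003,
                inter_droplet_gap=0.015,
                seed=2,
            )
        )[0]
        counts = [
            len(detect_peaks(trace, DetectorConfig(baseline_window=100,
                                                   threshold_multiple=k)))
            for k in (2.0, 3.0, 5.0, 8.0, 15.0, 40.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDriftImmunity:
    def _drifting_spec(self, n_pulses, noise_sd=0.01, window=100):
        # drift of 0.1 * noise_sd per baseline window
        rate = 0.1 * noise_sd / (window / 10_000.0)
        duration = 0.1 + 0.02 * n_pulses
        return TraceSpec(
            sample_rate=10_000.0,
            duration=duration,
            baseline_level=0.1,
            baseline_drift_rate=rate,
            noise_sd=noise_sd,
            pulses=tuple(
                Pulse(0.05 + 0.02 * i, 10 * noise_sd, 3e-4) for i in range(n_pulses)
            ),
            seed=17,
        )

    def test_baseline_tracks_drift_with_pulses(self):
        # 20 pulses on a slowly drifting baseline: all 20 detected and the
        # final baseline estimate stays within 3*noise_sd of ground truth
        noise_sd = 0.01
        spec = self._drifting_spec(20, noise_sd=noise_sd)
        trace = make_trace(spec)
        cfg = DetectorConfig(baseline_window=100)
        det = PeakDetector(cfg, trace.dt)
        det.process(trace.time, trace.signal)
        peaks = det.finalize()
        assert len(peaks) == 20
        true_end = spec.baseline_at(trace.time[-1])
        assert abs(det.baseline - true_end) < 3 * noise_sd

        # independent oracle: offline moving average over ground-truth
        # pulse-free samples agrees with the streaming estimate
        pulse_free = np.ones(trace.n_samples, dtype=bool)
        for p in spec.pulses:
            pulse_free &= np.abs(trace.time - p.center_time) > 6 * p.width_sd
        oracle_window = trace.signal[pulse_free][-cfg.baseline_window:]
        oracle = oracle_window.mean()
        assert abs(det.baseline - oracle) < 3 * noise_sd

    def test_pulse_free_drift_tracked_everywhere(self):
        noise_sd = 0.01
        spec = TraceSpec(
            sample_rate=10_000.0, duration=1.0, baseline_level=0.1,
            baseline_drift_rate=0.05, noise_sd=noise_sd, seed=23,
        )
        trace = make_trace(spec)
        cfg = DetectorConfig(baseline_window=100)
        det = PeakDetector(cfg, trace.dt)
        errs = []
        for i in range(trace.n_samples):
            det.process(trace.time[i : i + 1], trace.signal[i : i + 1])
            if i >= cfg.baseline_window:
                errs.append(abs(det.baseline - spec.baseline_at(trace.time[i])))
        assert max(errs) < 3 * noise_sd

    def test_ablated_detector_shows_larger_terminal_error(self):
        # contrast test: feeding peak samples into the baseline average drags
        # the estimate upward on a pulse-dense trace
        # pulses run all the way to the end of the trace so the ablated
        # window still holds in-peak samples at the terminal measurement
        noise_sd = 0.01
        spec = TraceSpec(
            sample_rate=10_000.0,
            duration=0.6,
            baseline_level=0.1,
            noise_sd=noise_sd,
            pulses=tuple(Pulse(0.05 + 0.005 * i, 1.0, 5e-4) for i in range(110)),
            seed=31,
        )
        trace = make_trace(spec)
        true_end = spec.baseline_at(trace.time[-1])

        def terminal_error(include_peaks):
            cfg = DetectorConfig(baseline_window=100,
                                 include_peaks_in_baseline=include_peaks)
            det = PeakDetector(cfg, trace.dt)
            det.process(trace.time, trace.signal)
            det.finalize()
            return abs(det.baseline - float(true_end))

        assert terminal_error(True) > terminal_error(False)


class TestStreamingEquivalence:
    def test_chunked_equals_single_pass(self):
        trace, _ = make_population_traces(
            PopulationSpec(
                groups=(GroupSpec((1.0, 0.5, 0.8), cv=0.1),),
                droplets_per_group=20,
                transit_spacing=0.003,
                inter_droplet_gap=0.015,
                seed=8,
            )
        )
        cfg = DetectorConfig(baseline_window=100)
        offline = detect_peaks(trace, cfg)

        rng = np.random.default_rng(0)
        det = PeakDetector(cfg, trace.dt)
        i = 0
        while i < trace.n_samples:
            n = int(rng.integers(1, 999))
            det.process(trace.time[i : i + n], trace.signal[i : i + n])
            i += n
        streamed = det.finalize()
        assert streamed == offline


class TestGroupPeaks:
    def _peak(self, t, mag=1.0):
        return Peak(t, t + 1e-4, mag, 0.1)

    def test_three_close_peaks_one_signature(self):
        cfg = DetectorConfig(group_time=0.005)
        peaks = [self._peak(0.0), self._peak(0.001), self._peak(0.002)]
        sigs = group_peaks(peaks, cfg)
        assert len(sigs) == 1
        assert sigs[0].complete

    def test_distant_peaks_incomplete_signatures(self):
        cfg = DetectorConfig(group_time=0.005)
        peaks = [self._peak(0.0), self._peak(0.010)]
        sigs = group_peaks(peaks, cfg)
        assert len(sigs) == 2
        assert all(not s.complete for s in sigs)
        assert all(s.magnitudes[1:] == (0.0, 0.0) for s in sigs)

    def test_empty_input(self):
        assert group_peaks([], DetectorConfig()) == []

    def test_two_droplets_match_ground_truth(self):
        spec = PopulationSpec(
            groups=(GroupSpec((1.0, 0.6, 0.3)),),
            droplets_per_group=2,
            transit_spacing=0.012,
            inter_droplet_gap=0.05,
            noise_sd=0.01,
            seed=1,
        )
        trace, truth = make_population_traces(spec)
        cfg = DetectorConfig(baseline_window=100, group_time=0.03)
        sigs = group_peaks(detect_peaks(trace, cfg), cfg)
        assert len(sigs) == 2
        assert all(s.complete for s in sigs)
        matched = match_signatures_to_truth(sigs, truth, cfg.group_time)
        assert len(matched) == 2
        for sig, rec in matched:
            for m, h in zip(sig.magnitudes, rec.pulse_heights):
                assert abs(m - h) <= spec.noise_sd


class TestDetectorScore:
    def test_perfect_detection_noise_free(self):
        spec = PopulationSpec(
            groups=(GroupSpec((1.0, 1.0, 1.0)),),
            droplets_per_group=5,
            transit_spacing=0.003,
            inter_droplet_gap=0.02,
            noise_sd=0.001,
            seed=6,
        )
        trace, truth = make_population_traces(spec)
        cfg = DetectorConfig(baseline_window=100, group_time=0.008)
        sigs = group_peaks(detect_peaks(trace, cfg), cfg)
        recall, precision, rmse = detector_score(sigs, truth, cfg.group_time)
        assert recall == 1.0
        assert precision == 1.0
        assert rmse < 0.01

    def test_unreachable_threshold_zero_recall(self, eight_group_spec):
        trace, truth = make_population_traces(eight_group_spec)
        cfg = DetectorConfig(baseline_window=100, threshold_multiple=1e6)
        sigs = group_peaks(detect_peaks(trace, cfg), cfg)
        recall, _, _ = detector_score(sigs, truth, cfg.group_time)
        assert recall == 0.0

    def test_recall_at_snr_10_on_400_droplets(self):
        # pulse heights 10x the noise SD, 400 droplets; pulse spacing exceeds
        # the baseline window so shoulders flush out between pulses
        noise_sd = 0.01
        spec = PopulationSpec(
            groups=tuple(
                GroupSpec((10 * noise_sd,) * 3, cv=0.05) for _ in range(8)
            ),
            droplets_per_group=50,
            transit_spacing=0.012,
            inter_droplet_gap=0.05,
            noise_sd=noise_sd,
            seed=77,
        )
        trace, truth = make_population_traces(spec)
        cfg = DetectorConfig(baseline_window=100, group_time=0.03)
        sigs = group_peaks(detect_peaks(trace, cfg), cfg)
        recall, precision, _ = detector_score(sigs, truth, cfg.group_time)
        assert recall >= 0.99
        assert precision >= 0.99
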