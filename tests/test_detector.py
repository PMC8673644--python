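"""Impulse detector: filtering, event logic, extraction, RL diagnostics."""

import numpy as np
import pytest

from clickchain import audio_io, detector, pipeline, simulate
from clickchain.audio_io import AudioChunk
from clickchain.detector import DetectorParams, Event

from conftest import click_spec, small_scene


def sine_chunk(freq, fs=200_000, seconds=0.1, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return AudioChunk(amp * np.sin(2 * np.pi * freq * t), 0.0, fs)


class TestBandpass:
    def test_passband_tone_preserved_within_1db(self):
        out = detector.bandpass(sine_chunk(50_000), DetectorParams())
        rms_ratio = np.sqrt(np.mean(out.samples[2000:] ** 2)) / np.sqrt(0.5)
        assert abs(20 * np.log10(rms_ratio)) < 1.0

    def test_stopband_tone_attenuated_40db(self):
        out = detector.bandpass(sine_chunk(1_000), DetectorParams())
        rms_ratio = np.sqrt(np.mean(out.samples[5000:] ** 2)) / np.sqrt(0.5)
        assert 20 * np.log10(rms_ratio) < -40.0

    def test_zeros_map_to_zeros(self):
        out = detector.bandpass(AudioChunk(np.zeros(1000), 0.0, 200_000), DetectorParams())
        np.testing.assert_allclose(out.samples, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            detector.bandpass(AudioChunk(np.zeros(10), 0.0, 48_000), DetectorParams())

    @pytest.mark.parametrize("fs", [96_000, 200_000, 500_000])
    def test_impulse_response_decays_without_overflow(self, fs):
        params = DetectorParams(band_high=min(100_000, fs / 2 - 1000))
        x = np.zeros(int(0.05 * fs))
        x[100] = 1e6
        out = detector.bandpass(AudioChunk(x, 0.0, fs), params)
        assert np.all(np.isfinite(out.samples))
        assert np.max(np.abs(out.samples[-100:])) < 1e-3 * np.max(np.abs(out.samples))


class TestEventLogic:
    def test_gap_below_merge_threshold_merges(self):
        evs = [Event(0.0, 100e-6, 50e-6), Event(150e-6, 250e-6, 200e-6)]
        merged = detector.merge_events(evs, 100e-6)
        assert len(merged) == 1
        assert merged[0].start_s == 0.0 and merged[0].end_s == pytest.approx(250e-6)

    def test_gap_above_merge_threshold_keeps_separate(self):
        evs = [Event(0.0, 100e-6, 50e-6), Event(300e-6, 400e-6, 350e-6)]
        assert len(detector.merge_events(evs, 100e-6)) == 2

    def test_merge_empty_and_idempotent(self):
        assert detector.merge_events([], 100e-6) == []
        evs = [Event(0.0, 100e-6, 50e-6), Event(150e-6, 250e-6, 200e-6)]
        once = detector.merge_events(evs, 100e-6)
        assert detector.merge_events(once, 100e-6) == once

    @pytest.mark.parametrize(
        "duration_us,kept", [(20, False), (300, True), (1500, False)]
    )
    def test_duration_window(self, duration_us, kept):
        ev = Event(0.0, duration_us * 1e-6, duration_us * 5e-7)
        out = detector.duration_filter([ev], DetectorParams())
        assert (len(out) == 1) == kept


class TestExtraction:
    def test_sine_snippet_rl_is_peak_to_peak_definition(self):
        fs = 200_000
        chunk = sine_chunk(50_000, fs=fs, seconds=0.01, amp=1.0)
        ev = Event(0.004, 0.0045, 0.00425)
        params = DetectorParams(rl_threshold_pp=0.0)
        det = detector.extract_detection(chunk, ev, params)
        assert det.rl_pp == pytest.approx(20 * np.log10(2), abs=0.01)

    def test_click_spectrum_peaks_at_center_frequency(self):
        fs = 200_000
        params = DetectorParams(rl_threshold_pp=0.0)
        w = simulate.synth_click(click_spec(center_freq=40_000), fs, 130.0)
        x = np.zeros(int(0.01 * fs))
        x[1000 : 1000 + len(w)] = w
        ev = Event(1000 / fs, (1000 + len(w)) / fs, (1000 + len(w) // 2) / fs)
        det = detector.extract_detection(AudioChunk(x, 0.0, fs), ev, params)
        freqs = params.spectrum_freqs()
        assert abs(freqs[np.argmax(det.spectrum)] - 40_000) <= params.spectrum_bin

    def test_spectrum_length_matches_band_grid(self):
        fs = 200_000
        params = DetectorParams()  # 5-100 kHz, 500-Hz bins
        x = np.zeros(int(0.01 * fs))
        x[1000] = 10 ** (125 / 20)
        det = detector.extract_detection(
            AudioChunk(x, 0.0, fs), Event(1000 / fs, 1010 / fs, 1005 / fs), params
        )
        assert len(det.spectrum) == 191
        assert len(params.spectrum_freqs()) == 191


class TestDetectionOnScenes:
    def test_click_above_threshold_detected_once(self, tmp_path):
        _, wav, truth = small_scene(tmp_path, duration=5.0, min_rl=125.0)
        table, _ = pipeline.detect_scene(wav, pipeline.demo_detector_params(48_000))
        assert len(table) == len(truth)

    def test_click_below_threshold_ignored(self):
        fs = 48_000
        params = pipeline.demo_detector_params(fs)
        w = simulate.synth_click(
            click_spec(center_freq=15_000, bandwidth=3_000, duration=250e-6), fs, 119.0
        )
        x = np.random.default_rng(0).normal(0, 10.0, fs)  # negligible floor
        x[10_000 : 10_000 + len(w)] += w
        dets = detector.detect_chunk(AudioChunk(x, 0.0, fs), params)
        assert dets == []

    def test_pure_noise_produces_no_events(self):
        fs = 48_000
        sigma = np.sqrt(10 ** (50 / 10) * fs / 2)  # 50 dB re 1 µPa²/Hz floor
        x = np.random.default_rng(1).normal(0, sigma, 2 * fs)
        dets = detector.detect_chunk(AudioChunk(x, 0.0, fs), pipeline.demo_detector_params(fs))
        assert dets == []

    def test_chunking_invariance(self, tmp_path):
        cfg, wav, truth = small_scene(tmp_path, duration=6.0, min_rl=128.0)
        params = pipeline.demo_detector_params(cfg.fs)
        t_small, _ = pipeline.detect_scene(wav, params, chunk_seconds=1.0)
        t_big, _ = pipeline.detect_scene(wav, params, chunk_seconds=6.0)
        assert len(t_small) == len(t_big)
        # chunk-edge filter transients may move values by a hair
        np.testing.assert_allclose(t_small["time_s"], t_big["time_s"], atol=5e-5)
        np.testing.assert_allclose(t_small["rl_pp_db"], t_big["rl_pp_db"], atol=0.01)


class TestRLDiagnostic:
    def test_uniform_area_levels_pass(self):
        rl = simulate.sample_received_levels(5_000, 120, 170, 3)
        _, _, flag = detector.rl_distribution_diagnostic(rl, threshold=120)
        assert flag == "pass"

    def test_censored_levels_fail(self):
        rl = simulate.sample_received_levels(5_000, 120, 170, 3)
        _, _, flag = detector.rl_distribution_diagnostic(rl[rl >= 123], threshold=120)
        assert flag == "fail"

    def test_insufficient_data_flagged(self):
        rl = np.full(99, 125.0)
        _, _, flag = detector.rl_distribution_diagnostic(rl, threshold=120)
        assert flag == "insufficient data"
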