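"""Generic impulse detector for calibrated hydrophone audio.

The detection chain: band-pass the pressure series with a five-pole
Butterworth filter (default 5–100 kHz); find regions where the Hilbert
envelope exceeds the peak-equivalent of the peak-to-peak received-level
threshold (default 120 dB pp re 1 µPa); merge events separated by less
than ``merge_gap`` (default 100 µs); keep events with envelope-crossing
durations between 30 and 1200 µs; verify the peak-to-peak criterion on a
fixed-length snippet (default 1 ms) centred on the envelope peak; and
compute each event's spectrum on a 500-Hz grid across the detection band.

A received-level distribution diagnostic checks the hallmark of a healthy
threshold choice: under spherical spreading with animals uniform over
area, detection counts per dB grow toward the threshold, so a histogram
that rolls off just above the threshold indicates systematic misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .audio_io import AudioChunk


@dataclass
class DetectorParams:
    band_low: float = 5_000.0
    band_high: float = 100_000.0
    filter_order: int = 5
    rl_threshold_pp: float = 120.0  # dB pp re 1 µPa
    min_duration: float = 30e-6
    max_duration: float = 1200e-6
    merge_gap: float = 100e-6
    snippet_duration: float = 1e-3
    spectrum_bin: float = 500.0
    zero_phase: bool = False

    def validate(self, fs: float) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high > fs / 2:
            raise ValueError(f"band_high {self.band_high:.0f} Hz exceeds Nyquist {fs / 2:.0f} Hz")
        if not (0 < self.min_duration < self.max_duration):
            raise ValueError("need 0 < min_duration < max_duration")

    @property
    def threshold_pp_upa(self) -> float:
        return 10 ** (self.rl_threshold_pp / 20)

    def spectrum_freqs(self) -> np.ndarray:
        n = int(np.floor((self.band_high - self.band_low) / self.spectrum_bin)) + 1
        return self.band_low + self.spectrum_bin * np.arange(n)


@dataclass
class Event:
    """Raw threshold-crossing extent (seconds from file start)."""

    start_s: float
    end_s: float
    peak_s: float

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Detection:
    id: int
    time_s: float
    start_s: float
    end_s: float
    snippet: np.ndarray
    envelope: np.ndarray
    spectrum: np.ndarray
    rl_pp: float

    @property
    def duration_us(self) -> float:
        return (self.end_s - self.start_s) * 1e6


def design_bandpass(params: DetectorParams, fs: float) -> np.ndarray:
    params.validate(fs)
    # a band edge exactly at Nyquist is legal (HARP-style 100 kHz at
    # fs 200 kHz) but degenerate for the design; nudge it just below
    high = min(params.band_high, 0.999 * fs / 2)
    return signal.butter(
        params.filter_order, [params.band_low, high], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(chunk: AudioChunk, params: DetectorParams, sos: np.ndarray | None = None) -> AudioChunk:
    """Five-pole Butterworth band-pass; causal by default (``zero_phase`` option)."""
    if sos is None:
        sos = design_bandpass(params, chunk.fs)
    filt = signal.sosfiltfilt(sos, chunk.samples) if params.zero_phase else signal.sosfilt(sos, chunk.samples)
    return replace(chunk, samples=filt)


def envelope_of(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert envelope)."""
    return np.abs(signal.hilbert(x))


def detect_events(chunk: AudioChunk, params: DetectorParams, env: np.ndarray | None = None) -> list[Event]:
    """Contiguous envelope excursions above the peak-equivalent threshold.

    The pp criterion itself is enforced later on the extracted snippet;
    here an event is any region where the envelope exceeds half the linear
    pp-threshold amplitude, which defines the event's duration.
    """
    if env is None:
        env = envelope_of(chunk.samples)
    amp = params.threshold_pp_upa / 2
    above = env > amp
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks], [idx[-1]]))
    fs = chunk.fs
    t0 = chunk.start_time
    events = []
    for s, e in zip(run_starts, run_ends):
        peak = s + int(np.argmax(env[s : e + 1]))
        events.append(Event(t0 + s / fs, t0 + (e + 1) / fs, t0 + peak / fs))
    return events


def merge_events(events: Sequence[Event], merge_gap: float) -> list[Event]:
    """Merge events whose inter-event gap is ≤ ``merge_gap``; idempotent."""
    if not events:
        return []
    events = sorted(events, key=lambda e: e.start_s)
    merged = [events[0]]
    for ev in events[1:]:
        last = merged[-1]
        if ev.start_s - last.end_s <= merge_gap:
            peak = last.peak_s  # keep the earlier peak; refined at extraction
            merged[-1] = Event(last.start_s, max(last.end_s, ev.end_s), peak)
        else:
            merged.append(ev)
    return merged


def duration_filter(events: Iterable[Event], params: DetectorParams) -> list[Event]:
    return [e for e in events if params.min_duration <= e.duration <= params.max_duration]


def extract_detection(
    chunk: AudioChunk,
    event: Event,
    params: DetectorParams,
    det_id: int = 0,
    env: np.ndarray | None = None,
) -> Detection | None:
    """Snippet/envelope/spectrum/received level for one event.

    Returns None when the event fails the peak-to-peak criterion. The
    snippet (fixed ``snippet_duration``) is centred on the envelope peak,
    zero-padded at file edges; RL_pp = 20·log10(max − min). The spectrum is
    the Hann-windowed periodogram of the snippet, zero-padded to
    fs/``spectrum_bin`` points so the native grid is exactly 500 Hz, in
    dB re 1 µPa²/Hz on [band_low, band_high].
    """
    fs = chunk.fs
    x = chunk.samples
    if env is None:
        env = envelope_of(x)
    n_snip = int(round(params.snippet_duration * fs))
    s = int(round((event.start_s - chunk.start_time) * fs))
    e = int(round((event.end_s - chunk.start_time) * fs))
    s, e = max(s, 0), min(e, len(x))
    if e <= s:
        return None
    peak = s + int(np.argmax(env[s:e]))
    lo = peak - n_snip // 2
    hi = lo + n_snip
    snippet = np.zeros(n_snip)
    src_lo, src_hi = max(lo, 0), min(hi, len(x))
    snippet[src_lo - lo : src_hi - lo] = x[src_lo:src_hi]
    pp = snippet.max() - snippet.min()
    if pp < params.threshold_pp_upa:
        return None
    rl_pp = 20 * np.log10(pp)
    snip_env = envelope_of(snippet)

    nfft = int(round(fs / params.spectrum_bin))
    win = np.hanning(n_snip)
    xw = snippet * win
    spec = np.fft.rfft(xw, n=max(nfft, n_snip))
    # periodogram scaling -> power spectral density, µPa²/Hz
    psd = (np.abs(spec) ** 2) / (fs * np.sum(win**2))
    psd[1:-1] *= 2
    df = fs / max(nfft, n_snip)
    idx = np.round(params.spectrum_freqs() / df).astype(int)
    with np.errstate(divide="ignore"):
        spectrum_db = 10 * np.log10(np.maximum(psd[idx], 1e-300))
    return Detection(
        id=det_id,
        time_s=chunk.start_time + peak / fs,
        start_s=event.start_s,
        end_s=event.end_s,
        snippet=snippet,
        envelope=snip_env,
        spectrum=spectrum_db,
        rl_pp=rl_pp,
    )


def detect_chunk(chunk: AudioChunk, params: DetectorParams, sos: np.ndarray | None = None) -> list[Detection]:
    """Full chain on one chunk, keeping only events the chunk owns."""
    filt = bandpass(chunk, params, sos=sos)
    env = envelope_of(filt.samples)
    events = detect_events(filt, params, env=env)
    events = merge_events(events, params.merge_gap)
    events = duration_filter(events, params)
    out = []
    for ev in events:
        if not (chunk.own_start <= ev.start_s < chunk.own_end):
            continue
        det = extract_detection(filt, ev, params, env=env)
        if det is not None:
            out.append(det)
    return out


def run_detector(
    chunks: Iterator[AudioChunk], params: DetectorParams, file_label: str = ""
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Detect over a calibrated chunk stream; returns (table, arrays).

    Ownership windows make the result independent of the chunking, provided
    the stream overlap is at least snippet_duration/2 + max_duration.
    """
    detections: list[Detection] = []
    sos = None
    for chunk in chunks:
        if sos is None:
            sos = design_bandpass(params, chunk.fs)
        detections.extend(detect_chunk(chunk, params, sos=sos))
    detections.sort(key=lambda d: d.start_s)
    rows = []
    snippets, envelopes, spectra = [], [], []
    for i, d in enumerate(detections):
        rows.append((i, file_label, d.time_s, d.start_s, d.end_s, d.rl_pp, d.duration_us))
        snippets.append(d.snippet)
        envelopes.append(d.envelope)
        spectra.append(d.spectrum)
    table = pd.DataFrame(
        rows, columns=["id", "file", "time_s", "start_s", "end_s", "rl_pp_db", "duration_us"]
    )
    arrays = {
        "snippet": np.asarray(snippets) if snippets else np.empty((0, 0)),
        "envelope": np.asarray(envelopes) if envelopes else np.empty((0, 0)),
        "spectrum": np.asarray(spectra) if spectra else np.empty((0, 0)),
    }
    return table, arrays


def rl_distribution_diagnostic(
    rl_values: np.ndarray,
    threshold: float,
    bin_width: float = 1.0,
    n_check: int = 5,
    min_detections: int = 100,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Sanity check that detection counts rise toward the RL threshold.

    Returns (counts, bin_edges, flag) with flag in {"pass", "fail",
    "insufficient data"}. The check fails when the counts in the lowest
    ``n_check`` bins are not nonincreasing with increasing RL — i.e. the
    distribution rolls off before reaching the threshold, the signature of
    clicks being systematically missed near it.
    """
    rl = np.asarray(rl_values, dtype=float)
    rl = rl[rl >= threshold]
    if len(rl) < min_detections:
        edges = threshold + bin_width * np.arange(2)
        counts, edges = np.histogram(rl, bins=edges) if len(rl) else (np.zeros(1, int), edges)
        return counts, edges, "insufficient data"
    top = np.ceil((rl.max() - threshold) / bin_width)
    edges = threshold + bin_width * np.arange(int(top) + 1)
    counts, edges = np.histogram(rl, bins=edges)
    k = min(n_check, len(counts))
    low = counts[:k]
    flag = "pass" if np.all(np.diff(low) <= 0) else "fail"
    return counts, edges, flag
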