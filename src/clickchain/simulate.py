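"""Synthetic underwater acoustic scenes with ground truth.

Generates single-channel pressure time series (WAV) containing Gaussian
background noise plus impulsive events — odontocete-like echolocation
clicks, ship-like broadband bursts and sonar-like narrowband pings —
organised into encounters, together with a truth table listing every
injected event. Received levels follow the uniform-area spatial model:
animals uniformly distributed around a stationary sensor give ranges with
density proportional to r, hence event counts per 1-dB received-level bin
that grow log-linearly (slope 1/10 per dB) toward the detection threshold.

All pressures are in µPa; levels are dB re 1 µPa (peak-to-peak for events)
or dB re 1 µPa²/Hz (noise spectral density).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio_io

CLICK_KINDS = ("click", "ship_like", "sonar_like")


@dataclass
class ClickClassSpec:
    """One synthetic signal class.

    ``source_level`` is dB pp re 1 µPa at the 1-m reference range;
    ``modal_idi`` / ``idi_jitter`` control the inter-detection-interval
    structure of a click train (seconds).
    """

    name: str
    center_freq: float
    bandwidth: float
    duration: float
    modal_idi: float
    idi_jitter: float
    source_level: float
    class_kind: str = "click"
    freq_jitter: float = 0.03  # per-event sd as fraction of center_freq
    duration_jitter: float = 0.10  # per-event sd as fraction of duration

    def validate(self, fs: float) -> None:
        if self.class_kind not in CLICK_KINDS:
            raise ValueError(f"unknown class_kind {self.class_kind!r}")
        if not (self.center_freq - self.bandwidth / 2 > 0):
            raise ValueError(f"{self.name}: band extends to or below 0 Hz")
        if not (self.center_freq + self.bandwidth / 2 < fs / 2):
            raise ValueError(
                f"{self.name}: band edge {self.center_freq + self.bandwidth / 2:.0f} Hz "
                f"at or above Nyquist ({fs / 2:.0f} Hz)"
            )
        if self.class_kind == "click" and not (30e-6 <= self.duration <= 1200e-6):
            raise ValueError(f"{self.name}: click duration outside [30, 1200] µs")
        if self.modal_idi <= self.duration:
            raise ValueError(f"{self.name}: modal_idi must exceed duration")


@dataclass
class Encounter:
    """A bout of one class's activity: [start_s, end_s) within the scene."""

    class_name: str
    start_s: float
    end_s: float


@dataclass
class SceneConfig:
    fs: float
    total_duration: float
    noise_floor: float  # dB re 1 µPa²/Hz
    classes: list[ClickClassSpec]
    encounters: list[Encounter]
    min_rl: float = 120.0  # dB pp re 1 µPa
    headroom_db: float = 9.0  # full scale above the loudest source level
    encounter_freq_jitter: float = 0.02  # per-encounter sd, fraction of center_freq
    seed: int = 0

    def validate(self) -> None:
        names = {c.name for c in self.classes}
        for c in self.classes:
            c.validate(self.fs)
            if self.min_rl >= c.source_level:
                raise ValueError(f"min_rl must be below source level of {c.name}")
        for e in self.encounters:
            if e.class_name not in names:
                raise ValueError(f"encounter references unknown class {e.class_name!r}")
            if not (0 <= e.start_s < e.end_s <= self.total_duration):
                raise ValueError("encounter outside [0, total_duration]")

    @property
    def full_scale_upa(self) -> float:
        """Pressure mapped to int16 full scale (loudest SL peak + headroom)."""
        sl = max(c.source_level for c in self.classes) if self.classes else self.min_rl
        return 10 ** ((sl + self.headroom_db) / 20) / 2

    @property
    def counts_per_upa(self) -> float:
        return 32767.0 / self.full_scale_upa


def synth_click(spec: ClickClassSpec, fs: float, rl_pp: float) -> np.ndarray:
    """Synthesize one event waveform (µPa) with exact peak-to-peak level.

    Clicks are Gabor pulses (Gaussian-windowed cosine): spectral peak at
    ``center_freq``, -3 dB spectral width ≈ ``bandwidth``. Ship-like events
    are low-frequency-weighted noise bursts; sonar-like events are
    Tukey-windowed narrowband pings. Peak-to-peak amplitude is scaled to
    exactly ``10**(rl_pp/20)`` µPa.
    """
    spec.validate(fs)
    n = max(int(round(spec.duration * fs)), 4)
    t = (np.arange(n) - (n - 1) / 2) / fs
    if spec.class_kind == "click":
        # sigma_t from the Gaussian time/frequency pair: FWHM_f = bandwidth
        sigma_t = 2.3548 / (2 * np.pi * spec.bandwidth)
        sigma_t = min(sigma_t, spec.duration / 6)  # keep the pulse inside its window
        w = np.exp(-(t**2) / (2 * sigma_t**2)) * np.cos(2 * np.pi * spec.center_freq * t)
    elif spec.class_kind == "sonar_like":
        win = _tukey(n, 0.25)
        w = win * np.cos(2 * np.pi * spec.center_freq * t)
    else:  # ship_like: deterministic broadband burst, energy weighted low
        win = _tukey(n, 0.5)
        # sum of decaying harmonics around center_freq gives a reproducible
        # broadband, low-frequency-weighted burst
        freqs = spec.center_freq + np.linspace(-0.5, 0.5, 7) * spec.bandwidth
        amps = 1.0 / np.linspace(1.0, 2.5, 7)
        w = win * sum(a * np.cos(2 * np.pi * f * t + 0.7 * k) for k, (a, f) in enumerate(zip(amps, freqs)))
    pp = w.max() - w.min()
    return w * (10 ** (rl_pp / 20) / pp)


def _tukey(n: int, alpha: float) -> np.ndarray:
    from scipy.signal import windows

    return windows.tukey(n, alpha)


def sample_received_levels(
    n: int, min_rl: float, source_level: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw received levels (dB pp) for sources uniform over area.

    Ranges have density ∝ r out to the radius where spherical spreading
    brings the level down to ``min_rl``; RL = SL − 20·log10(r). The
    resulting counts per 1-dB bin grow by a factor 10^(1/10) per dB of
    decrease toward ``min_rl``.
    """
    if min_rl >= source_level:
        raise ValueError("min_rl must be below source_level")
    if n <= 0:
        return np.empty(0)
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    r_max = 10 ** ((source_level - min_rl) / 20)
    r = r_max * np.sqrt(rng.uniform(size=n))
    with np.errstate(divide="ignore"):
        rl = source_level - 20 * np.log10(r)
    return np.minimum(rl, source_level)  # sources inside the 1-m reference range clamp to SL


def _perturb(
    spec: ClickClassSpec, fs: float, rng: np.random.Generator, encounter_factor: float = 1.0
) -> ClickClassSpec:
    """Per-event variant of a class: real signals vary click to click."""
    from dataclasses import replace

    f0 = spec.center_freq * encounter_factor * (1 + rng.normal(0, spec.freq_jitter))
    f0 = float(np.clip(f0, spec.bandwidth / 2 + 100, fs / 2 - spec.bandwidth / 2 - 100))
    dur = spec.duration * (1 + rng.normal(0, spec.duration_jitter))
    lo, hi = (30e-6, 1200e-6) if spec.class_kind == "click" else (spec.duration / 2, spec.duration * 2)
    dur = float(np.clip(dur, lo, hi))
    return replace(spec, center_freq=f0, duration=dur, modal_idi=max(spec.modal_idi, dur * 2))


def _encounter_times(enc: Encounter, spec: ClickClassSpec, rng: np.random.Generator) -> np.ndarray:
    times = []
    t = enc.start_s
    while t + spec.duration <= enc.end_s:  # whole event inside the bout
        times.append(t)
        step = spec.modal_idi + rng.normal(0.0, spec.idi_jitter)
        t += max(step, spec.duration * 2)
    return np.asarray(times)


def build_truth(config: SceneConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Schedule every event of the scene: times, classes, received levels."""
    by_name = {c.name: c for c in config.classes}
    rows = []
    for enc_id, enc in enumerate(config.encounters):
        spec = by_name[enc.class_name]
        times = _encounter_times(enc, spec, rng)
        rls = sample_received_levels(len(times), config.min_rl, spec.source_level, rng)
        for t, rl in zip(times, rls):
            rows.append((t, enc.class_name, rl, enc_id))
    truth = pd.DataFrame(rows, columns=["time_s", "class", "rl_pp_db", "encounter_id"])
    return truth.sort_values(["time_s", "encounter_id"], kind="stable").reset_index(drop=True)


def synth_scene(
    config: SceneConfig, out_dir: str | Path, basename: str = "scene", chunk_seconds: float = 30.0
) -> tuple[Path, pd.DataFrame]:
    """Render a scene to WAV + truth CSV + calibration sidecar.

    Noise and events are synthesized in fixed 30-s blocks and streamed to a
    16-bit PCM file, so scenes of hours need only block-sized memory. The
    block partition is part of the determinism contract: a fixed seed gives
    byte-identical output.

    Returns (wav_path, truth_table). Raises if any block would clip; lower
    the source levels or raise ``headroom_db`` in that case.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = build_truth(config, rng)

    fs = config.fs
    noise_sigma = np.sqrt(10 ** (config.noise_floor / 10) * fs / 2)
    by_name = {c.name: c for c in config.classes}
    # per-encounter frequency offset: different animal groups / sources of
    # one class are alike but not identical between bouts
    enc_factor = {
        eid: 1 + rng.normal(0, config.encounter_freq_jitter) for eid in range(len(config.encounters))
    }
    waveforms = {}
    for i, (cls, rl, eid) in enumerate(zip(truth["class"], truth["rl_pp_db"], truth["encounter_id"])):
        waveforms[i] = synth_click(
            _perturb(by_name[cls], fs, rng, enc_factor[eid]), fs, rl
        )
    starts = (truth["time_s"].to_numpy() * fs).round().astype(np.int64)
    lens = np.array([len(waveforms[i]) for i in range(len(truth))], dtype=np.int64)

    n_total = int(round(config.total_duration * fs))
    block = int(round(chunk_seconds * fs))
    wav_path = out_dir / f"{basename}.wav"
    scale = config.counts_per_upa
    with audio_io.open_wav_writer(wav_path, fs) as writer:
        for b0 in range(0, n_total, block):
            b1 = min(b0 + block, n_total)
            buf = rng.normal(0.0, noise_sigma, b1 - b0)
            hit = np.nonzero((starts < b1) & (starts + lens > b0))[0]
            for i in hit:
                w = waveforms[i]
                s = starts[i]
                lo, hi = max(s, b0), min(s + len(w), b1)
                buf[lo - b0 : hi - b0] += w[lo - s : hi - s]
            counts = buf * scale
            if np.abs(counts).max() > 32767:
                raise OverflowError(
                    "scene clips at int16 full scale; lower source levels or raise headroom_db"
                )
            writer.write(np.round(counts).astype(np.int16))
    audio_io.write_calibration(wav_path, scale)
    truth.to_csv(out_dir / f"{basename}_truth.csv", index=False)
    with open(out_dir / f"{basename}_config.json", "w") as fh:
        json.dump({"fs": fs, "seed": config.seed, "min_rl": config.min_rl}, fh)
    return wav_path, truth
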