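"""Streaming WAV I/O, calibration, and tabular detection products.

Audio is 16-bit (or 24-bit) PCM mono WAV. A flat hydrophone sensitivity
(counts per µPa) is carried in a JSON sidecar next to each WAV file, since
the format itself cannot record physical units; dividing raw counts by it
recovers pressure in µPa. Time is seconds from file start, 0-based, with
half-open intervals throughout.

Detection tables are CSV; the fixed-length per-detection arrays (snippet,
envelope, spectrum) live in raw float32 row-major sidecar files described
by a small JSON header, so round-trips are bit-exact.
"""

from __future__ import annotations

import contextlib
import json
import wave
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

DETECTION_COLUMNS = ["id", "file", "time_s", "start_s", "end_s", "rl_pp_db", "duration_us"]
ARRAY_KINDS = ("snippet", "envelope", "spectrum")


@dataclass
class AudioChunk:
    """Calibrated pressure samples (µPa) starting at ``start_time`` seconds.

    ``own_start``/``own_end`` delimit the half-open ownership window: the
    chunks a stream yields physically overlap so events spanning a chunk
    boundary are seen whole, but each instant of the file is *owned* by
    exactly one chunk, and detectors keep only events starting inside it.
    """

    samples: np.ndarray
    start_time: float
    fs: float
    own_start: float = 0.0
    own_end: float = np.inf

    @property
    def end_time(self) -> float:
        return self.start_time + len(self.samples) / self.fs


class CalibrationError(RuntimeError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".cal.json")


def write_calibration(wav_path: str | Path, counts_per_upa: float) -> Path:
    p = _sidecar(Path(wav_path))
    with open(p, "w") as fh:
        json.dump({"counts_per_upa": counts_per_upa}, fh)
    return p


def read_calibration(wav_path: str | Path) -> float:
    p = _sidecar(Path(wav_path))
    if not p.exists():
        raise CalibrationError(f"missing calibration sidecar {p}")
    with open(p) as fh:
        return float(json.load(fh)["counts_per_upa"])


@contextlib.contextmanager
def open_wav_writer(path: str | Path, fs: float):
    """Incremental 16-bit mono PCM writer; ``.write(int16_array)`` appends."""

    class _W:
        def __init__(self, wf):
            self._wf = wf

        def write(self, samples: np.ndarray):
            if samples.dtype != np.int16:
                raise TypeError("expected int16 samples")
            self._wf.writeframes(samples.tobytes())

    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(int(round(fs)))
        yield _W(wf)


def wav_info(path: str | Path) -> tuple[float, int, int]:
    """(fs, n_frames, sample_width_bytes) of a mono PCM WAV."""
    with wave.open(str(path), "rb") as wf:
        if wf.getnchannels() != 1:
            raise ValueError("only mono WAV is supported")
        if wf.getsampwidth() not in (2, 3):
            raise ValueError("only 16/24-bit PCM WAV is supported")
        return float(wf.getframerate()), wf.getnframes(), wf.getsampwidth()


def _decode(frames: bytes, width: int) -> np.ndarray:
    if width == 2:
        return np.frombuffer(frames, dtype="<i2").astype(np.float64)
    raw = np.frombuffer(frames, dtype=np.uint8).reshape(-1, 3)
    vals = raw[:, 0].astype(np.int32) | (raw[:, 1].astype(np.int32) << 8) | (
        raw[:, 2].astype(np.int32) << 16
    )
    vals = np.where(vals >= 1 << 23, vals - (1 << 24), vals)
    return vals.astype(np.float64)


def stream_audio(
    path: str | Path,
    chunk_seconds: float,
    overlap_seconds: float,
    counts_per_upa: float | None = None,
) -> Iterator[AudioChunk]:
    """Yield calibrated chunks covering the whole file.

    Chunk *k* owns the window [k·C, (k+1)·C) (C = ``chunk_seconds``) and is
    padded by ``overlap_seconds`` of context on each side, so events within
    ``overlap_seconds`` of a boundary are fully visible in the chunk that
    owns their start time. The number of chunks is ceil(duration / C).
    """
    path = Path(path)
    if chunk_seconds <= overlap_seconds:
        raise ValueError("chunk_seconds must exceed overlap_seconds")
    if counts_per_upa is None:
        counts_per_upa = read_calibration(path)
    fs, n_frames, width = wav_info(path)
    step = int(round(chunk_seconds * fs))
    pad = int(round(overlap_seconds * fs))
    with wave.open(str(path), "rb") as wf:
        for k, own0 in enumerate(range(0, n_frames, step)):
            own1 = min(own0 + step, n_frames)
            lo = max(own0 - pad, 0)
            hi = min(own1 + pad, n_frames)
            wf.setpos(lo)
            samples = _decode(wf.readframes(hi - lo), width) / counts_per_upa
            yield AudioChunk(
                samples=samples,
                start_time=lo / fs,
                fs=fs,
                own_start=own0 / fs,
                own_end=own1 / fs if own1 < n_frames else np.inf,
            )


def read_wav_pressure(path: str | Path, counts_per_upa: float | None = None) -> tuple[np.ndarray, float]:
    """Whole file as calibrated pressure (µPa). Returns (samples, fs)."""
    if counts_per_upa is None:
        counts_per_upa = read_calibration(path)
    fs, n_frames, width = wav_info(path)
    with wave.open(str(Path(path)), "rb") as wf:
        samples = _decode(wf.readframes(n_frames), width) / counts_per_upa
    return samples, fs


# ---------------------------------------------------------------------------
# detection tables


class SchemaError(ValueError):
    pass


def write_detection_table(
    csv_path: str | Path,
    table: pd.DataFrame,
    arrays: dict[str, np.ndarray] | None = None,
) -> None:
    """CSV + raw float32 sidecars (one fixed-length row per detection).

    Layout of each ``<stem>.<kind>.f32``: ``n_rows * row_len`` little-endian
    float32 values, row-major; shapes recorded in ``<stem>.arrays.json``.
    """
    csv_path = Path(csv_path)
    missing = [c for c in DETECTION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"detection table missing columns: {missing}")
    table.to_csv(csv_path, index=False, float_format="%.17g")  # exact float round-trip
    if arrays is None:
        return
    meta = {}
    for kind, arr in arrays.items():
        if kind not in ARRAY_KINDS:
            raise SchemaError(f"unknown array kind {kind!r}")
        arr = np.ascontiguousarray(arr, dtype="<f4")
        if arr.ndim != 2 or arr.shape[0] != len(table):
            raise SchemaError(f"{kind}: expected ({len(table)}, L) array")
        arr.tofile(csv_path.with_suffix(f".{kind}.f32"))
        meta[kind] = {"shape": list(arr.shape), "dtype": "<f4"}
    with open(csv_path.with_suffix(".arrays.json"), "w") as fh:
        json.dump(meta, fh)


def read_detection_table(csv_path: str | Path) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path, float_precision="round_trip")
    if len(table) == 0:
        table = pd.DataFrame(columns=DETECTION_COLUMNS)
    missing = [c for c in DETECTION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"detection table missing columns: {missing}")
    arrays: dict[str, np.ndarray] = {}
    meta_path = csv_path.with_suffix(".arrays.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        for kind, m in meta.items():
            arrays[kind] = np.fromfile(
                csv_path.with_suffix(f".{kind}.f32"), dtype=m["dtype"]
            ).reshape(m["shape"])
    return table, arrays
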