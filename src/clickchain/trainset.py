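"""Encounter-aware training-set assembly for the classifiers.

Labeled detections are first grouped into encounters — bouts of one
class's activity separated by at least 15 min (default) without that
class. Encounters, not detections, are the unit of the train/validation/
test split (default 60/10/30%), which prevents temporally correlated
detections of one animal group from leaking across splits. Training sets
are balanced by class, resampling with replacement (flagged) when a class
is short of examples.

Input vectors: a detection is its dB spectrum standardized by the typical
70–130 dB re 1 µPa²/Hz range, concatenated with its waveform snippet
scaled by a typical maximum pressure; a bin summary is the concatenation
of its normalized mean spectrum, IDI histogram (rescaled to peak 1) and
mean envelope, all already in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phase1 import BinClusterSummary

log = logging.getLogger(__name__)

SPECTRUM_LOW_DB = 70.0
SPECTRUM_HIGH_DB = 130.0
WAVEFORM_MAX_UPA = 10 ** (132 / 20)  # typical maximum pressure, µPa


@dataclass
class Encounter:
    encounter_id: int
    label: str
    start_s: float
    end_s: float
    item_idx: np.ndarray  # indices into the labeled-item table


@dataclass
class TrainingSet:
    X: np.ndarray  # (n, d) standardized input vectors
    y: np.ndarray  # integer classes 0..N-1
    class_names: list[str]
    encounter_ids: np.ndarray  # provenance per row
    resampled_classes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)


def split_encounters(times: np.ndarray, labels: np.ndarray, gap_s: float = 900.0) -> list[Encounter]:
    """Cut each class's detection sequence at silent gaps ≥ ``gap_s``."""
    times = np.asarray(times, dtype=float)
    labels = np.asarray(labels)
    encounters: list[Encounter] = []
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        order = idx[np.argsort(times[idx], kind="stable")]
        t = times[order]
        cut = np.flatnonzero(np.diff(t) >= gap_s)
        bounds = np.concatenate(([0], cut + 1, [len(order)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = order[a:b]
            encounters.append(
                Encounter(len(encounters), str(lab), float(t[a]), float(t[b - 1]), members)
            )
    return encounters


def partition_encounters(
    encounters: list[Encounter],
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int | np.random.Generator = 0,
) -> dict[int, str]:
    """Assign encounters to train/val/test per class in the given proportions.

    Largest-remainder rounding per class; when a class has ≥ 3 encounters,
    every split receives at least one. Returns encounter_id → split name.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    names = ("train", "val", "test")
    assignment: dict[int, str] = {}
    by_class: dict[str, list[Encounter]] = {}
    for e in encounters:
        by_class.setdefault(e.label, []).append(e)
    for lab, encs in by_class.items():
        n = len(encs)
        exact = np.array(fractions) * n
        counts = np.floor(exact).astype(int)
        rem = exact - counts
        for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
            counts[i] += 1
        if n >= 3 and (counts == 0).any():
            for i in np.flatnonzero(counts == 0):
                counts[int(np.argmax(counts))] -= 1
                counts[i] += 1
        if n < 3:
            log.warning("class %r has only %d encounters; some splits are empty", lab, n)
        order = rng.permutation(n)
        pos = 0
        for split, c in zip(names, counts):
            for k in order[pos : pos + c]:
                assignment[encs[k].encounter_id] = split
            pos += c
    return assignment


def sample_balanced(
    pool_idx: dict[str, np.ndarray],
    n_per_class: int,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Exactly ``n_per_class`` item indices per class.

    Sampling is without replacement when the pool suffices, with
    replacement otherwise; classes that needed resampling are returned in
    the flag list.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    out: dict[str, np.ndarray] = {}
    resampled: list[str] = []
    for lab, idx in pool_idx.items():
        idx = np.asarray(idx)
        if n_per_class == 0 or len(idx) == 0:
            out[lab] = np.empty(0, dtype=int)
            continue
        if len(idx) >= n_per_class:
            out[lab] = rng.choice(idx, size=n_per_class, replace=False)
        else:
            out[lab] = rng.choice(idx, size=n_per_class, replace=True)
            resampled.append(lab)
            log.info("class %r resampled with replacement (%d -> %d)", lab, len(idx), n_per_class)
    return out, resampled


def build_detection_input(
    spectrum_db: np.ndarray,
    snippet: np.ndarray,
    spectrum_low: float = SPECTRUM_LOW_DB,
    spectrum_high: float = SPECTRUM_HIGH_DB,
    waveform_max: float = WAVEFORM_MAX_UPA,
    range_normalize: bool = False,
) -> np.ndarray:
    """Concatenate standardized spectrum and scaled waveform snippet.

    The default follows the literal standardization rule — subtract the
    low typical value (70 dB) and divide by the high one (130 dB);
    ``range_normalize`` divides by the 60-dB range instead. Both keep most
    values within [−1, 1].
    """
    div = (spectrum_high - spectrum_low) if range_normalize else spectrum_high
    spec = (np.asarray(spectrum_db, dtype=float) - spectrum_low) / div
    wav = np.asarray(snippet, dtype=float) / waveform_max
    return np.concatenate([spec, wav])


def build_bin_input(summary: BinClusterSummary) -> np.ndarray:
    """Concatenate mean spectrum, IDI histogram (peak 1) and mean envelope."""
    idi = summary.idi_hist
    peak = idi.max()
    idi = idi / peak if peak > 0 else idi
    return np.concatenate([summary.mean_spectrum, idi, summary.mean_envelope])


def assemble(
    vectors: np.ndarray,
    labels: np.ndarray,
    times: np.ndarray,
    class_names: list[str],
    n_per_class: int,
    gap_s: float = 900.0,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
) -> dict[str, TrainingSet]:
    """Encounter split + balanced sampling → train/val/test TrainingSets.

    Asserts the leakage invariant: no encounter contributes rows to more
    than one split.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    encounters = split_encounters(times, labels, gap_s)
    assignment = partition_encounters(encounters, fractions, rng)
    item_encounter = np.full(len(labels), -1)
    for e in encounters:
        item_encounter[e.item_idx] = e.encounter_id
    item_split = np.array([assignment.get(eid, "train") for eid in item_encounter])

    out: dict[str, TrainingSet] = {}
    for split in ("train", "val", "test"):
        pool = {
            lab: np.flatnonzero((labels == lab) & (item_split == split)) for lab in class_names
        }
        pool = {lab: idx for lab, idx in pool.items() if len(idx) > 0}
        chosen, resampled = sample_balanced(pool, n_per_class, rng)
        rows = np.concatenate([chosen[lab] for lab in class_names if lab in chosen]) if chosen else np.empty(0, int)
        y = np.concatenate(
            [np.full(len(chosen[lab]), class_names.index(lab)) for lab in class_names if lab in chosen]
        ) if chosen else np.empty(0, int)
        out[split] = TrainingSet(
            X=vectors[rows],
            y=y,
            class_names=list(class_names),
            encounter_ids=item_encounter[rows],
            resampled_classes=resampled,
        )
    used: dict[int, set[str]] = {}
    for split, ts in out.items():
        for eid in np.unique(ts.encounter_ids):
            used.setdefault(int(eid), set()).add(split)
    leaks = {eid for eid, splits in used.items() if len(splits) > 1}
    assert not leaks, f"encounters leaked across splits: {sorted(leaks)}"
    return out
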