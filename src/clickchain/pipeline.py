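"""End-to-end orchestration on synthetic scenes.

Wires the full chain together — scene synthesis, streaming detection,
phase-1/phase-2 clustering, truth-based labeling of the discovered
templates (standing in for the analyst review step), encounter-aware
training-set assembly, classifier training and evaluation — and provides
the truth-matching helpers the evaluation needs (detections are matched
to injected events by time; a class is truly present in a bin when at
least ``min_bin_count`` of its events fall there, mirroring the
clustering minimum so the "none" accounting is well defined).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio_io, classifier, clustering, detector, evaluation, phase1, phase2, simulate, trainset


def demo_classes(fs: float = 48_000.0) -> list[simulate.ClickClassSpec]:
    """Five well-separated synthetic classes: four click types + a sonar-like ping."""
    return [
        simulate.ClickClassSpec("click_a", 8_500, 2_500, 300e-6, 0.15, 0.010, 150.0),
        simulate.ClickClassSpec("click_b", 12_000, 2_500, 220e-6, 0.20, 0.015, 150.0),
        simulate.ClickClassSpec("click_c", 16_000, 3_000, 150e-6, 0.09, 0.007, 150.0),
        simulate.ClickClassSpec("click_d", 20_000, 3_000, 400e-6, 0.25, 0.020, 150.0),
        simulate.ClickClassSpec(
            "sonar", 6_000, 800, 900e-6, 0.4, 0.020, 155.0, class_kind="sonar_like",
            freq_jitter=0.01, duration_jitter=0.05,  # man-made source: stable
        ),
    ]


def demo_scene_config(
    total_hours: float = 2.0,
    fs: float = 48_000.0,
    noise_floor: float = 50.0,
    min_rl: float = 126.0,
    seed: int = 0,
) -> simulate.SceneConfig:
    """Multi-class scene with overlapping encounters and 15-min-plus gaps.

    Each class recurs every 1200 s in a 250-s encounter; class offsets
    stagger the bouts so that different classes overlap in time while
    same-class bouts stay separated by 950 s of silence (> the 900-s
    encounter-splitting gap).
    """
    classes = demo_classes(fs)
    total = total_hours * 3600
    # offsets stagger the bouts so consecutive classes overlap and every
    # bout straddles a 300-s bin boundary (summaries in two bins per bout)
    offs = (80.0, 250.0, 430.0, 500.0, 760.0)
    offsets = {c.name: offs[i % len(offs)] for i, c in enumerate(classes)}
    encounters = []
    period, length = 1200.0, 250.0
    for c in classes:
        start = offsets[c.name]
        while start + length <= total:
            encounters.append(simulate.Encounter(c.name, start, start + length))
            start += period
    return simulate.SceneConfig(
        fs=fs,
        total_duration=total,
        noise_floor=noise_floor,
        classes=classes,
        encounters=encounters,
        min_rl=min_rl,
        encounter_freq_jitter=0.01,
        seed=seed,
    )


def demo_detector_params(fs: float = 48_000.0) -> detector.DetectorParams:
    """Detector band scaled to the demo sampling rate (full band below Nyquist).

    Zero-phase filtering is used here: the causal default distorts the
    peak-to-peak level of very short pulses by 1-2 dB through phase
    dispersion, and synthetic validation compares measured levels to truth.
    """
    return detector.DetectorParams(
        band_low=5_000.0, band_high=min(100_000.0, fs / 2 - 2_000.0), zero_phase=True
    )


def detect_scene(
    wav_path: str | Path, params: detector.DetectorParams, chunk_seconds: float = 10.0
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Stream a calibrated WAV through the detector."""
    overlap = 2 * (params.snippet_duration + params.max_duration)
    chunks = audio_io.stream_audio(wav_path, chunk_seconds, overlap)
    return detector.run_detector(chunks, params, file_label=Path(wav_path).name)


def match_detections_to_truth(
    det_times: np.ndarray, truth: pd.DataFrame, tol_s: float = 2e-3
) -> np.ndarray:
    """Index of the nearest truth event per detection (−1 if none within tol)."""
    truth_times = truth["time_s"].to_numpy()
    order = np.argsort(truth_times)
    sorted_times = truth_times[order]
    pos = np.searchsorted(sorted_times, det_times)
    best = np.full(len(det_times), -1)
    for i, (t, p) in enumerate(zip(det_times, pos)):
        cands = [j for j in (p - 1, p) if 0 <= j < len(sorted_times)]
        if not cands:
            continue
        j = min(cands, key=lambda j: abs(sorted_times[j] - t))
        if abs(sorted_times[j] - t) <= tol_s:
            best[i] = order[j]
    return best


def truth_labels_for_detections(
    table: pd.DataFrame, truth: pd.DataFrame, tol_s: float = 2e-3
) -> pd.Series:
    match = match_detections_to_truth(table["time_s"].to_numpy(), truth, tol_s)
    labels = np.where(match >= 0, truth["class"].to_numpy()[match], "noise")
    return pd.Series(labels, index=table.index, name="true_class")


def bins_truly_present(
    truth: pd.DataFrame, bin_duration: float = 300.0, min_bin_count: int = 50
) -> dict[int, list[str]]:
    """Classes truly present per bin (≥ ``min_bin_count`` events in the bin)."""
    b = np.floor(truth["time_s"].to_numpy() / bin_duration).astype(int)
    out: dict[int, list[str]] = {}
    counts = pd.DataFrame({"bin": b, "class": truth["class"]}).groupby(["bin", "class"]).size()
    for (bin_idx, cls), n in counts.items():
        if n >= min_bin_count:
            out.setdefault(int(bin_idx), []).append(cls)
    return out


def majority_label_map(
    templates: list[phase2.ClassTemplate],
    summaries: list[phase1.BinClusterSummary],
    det_truth: pd.Series,
    table: pd.DataFrame,
) -> tuple[dict[int, str], dict[int, float]]:
    """Truth-majority name and purity per template (the automated 'analyst').

    Purity is the fraction of a template's propagated detections whose
    truth class equals the template's majority class.
    """
    id_to_truth = pd.Series(det_truth.to_numpy(), index=table["id"].to_numpy())
    label_map: dict[int, str] = {}
    purity: dict[int, float] = {}
    for t in templates:
        member_ids = np.concatenate([summaries[i].member_ids for i in t.member_summary_idx])
        tl = id_to_truth.loc[member_ids]
        top = tl.value_counts()
        label_map[t.class_id] = str(top.index[0])
        purity[t.class_id] = float(top.iloc[0] / len(tl))
    return label_map, purity


@dataclass
class EndToEndResult:
    table: pd.DataFrame
    arrays: dict[str, np.ndarray]
    truth: pd.DataFrame
    summaries: list[phase1.BinClusterSummary]
    templates: list[phase2.ClassTemplate]
    label_map: dict[int, str]
    template_purity: dict[int, float]
    propagated: pd.DataFrame


def discover_classes(
    work_dir: str | Path,
    scene: simulate.SceneConfig,
    det_params: detector.DetectorParams | None = None,
    p1: phase1.Phase1Params | None = None,
    p2: phase2.Phase2Params | None = None,
) -> EndToEndResult:
    """Scene → detections → phase 1 → phase 2 → truth-labeled templates."""
    det_params = det_params or demo_detector_params(scene.fs)
    # dup_threshold > 1 disables near-duplicate merging: it is a size-reduction
    # device, unnecessary under the 2000-node cap, and its transitive closure
    # can chain overlapping classes within a bin
    p1 = p1 or phase1.Phase1Params(max_nodes=2_000, dup_threshold=1.1, seed=scene.seed)
    # retain_fraction scales with the scene: with ~65 summaries in 5 balanced
    # classes, within-class pairs are ~25% of all pairs, so a 10% retention
    # cannot keep every class connected; 20% keeps the within-class cliques
    # while between-class similarities still fall below the cutoff
    p2 = p2 or phase2.Phase2Params(min_phase2_size=5, retain_fraction=0.20, seed=scene.seed)
    wav_path, truth = simulate.synth_scene(scene, work_dir)
    table, arrays = detect_scene(wav_path, det_params)
    summaries = phase1.run_phase1(table, arrays, p1)
    _, templates, _ = phase2.cluster_summaries(summaries, p2)
    det_truth = truth_labels_for_detections(table, truth)
    label_map, purity = majority_label_map(templates, summaries, det_truth, table)
    templates, propagated = phase2.assign_labels(templates, summaries, label_map)
    return EndToEndResult(table, arrays, truth, summaries, templates, label_map, purity, propagated)


def detection_training_sets(
    result: EndToEndResult, n_per_class: int = 2_000, seed: int = 0
) -> tuple[dict[str, trainset.TrainingSet], list[str]]:
    """Detection-level train/val/test sets from the propagated labels."""
    prop = result.propagated.drop_duplicates("id")
    id_to_row = pd.Series(np.arange(len(result.table)), index=result.table["id"].to_numpy())
    rows = id_to_row.loc[prop["id"].to_numpy()].to_numpy()
    vectors = np.vstack(
        [
            trainset.build_detection_input(result.arrays["spectrum"][r], result.arrays["snippet"][r])
            for r in rows
        ]
    )
    labels = prop["label"].to_numpy()
    times = result.table["time_s"].to_numpy()[rows]
    class_names = sorted(set(labels.tolist()))
    sets = trainset.assemble(vectors, labels, times, class_names, n_per_class, seed=seed)
    return sets, class_names


def bin_training_sets(
    result: EndToEndResult, n_per_class: int = 64, seed: int = 0
) -> tuple[dict[str, trainset.TrainingSet], list[str], np.ndarray]:
    """Bin-level sets: one vector per labeled phase-1 summary.

    A summary's label is the label of the phase-2 template containing it;
    returns (sets, class_names, summary bin indices) so bin-level
    predictions can be aligned back to time bins.
    """
    labeled = []
    for t in result.templates:
        for si in t.member_summary_idx:
            labeled.append((si, t.label))
    idx = np.array([i for i, _ in labeled])
    labels = np.array([l for _, l in labeled])
    vectors = np.vstack([trainset.build_bin_input(result.summaries[i]) for i in idx])
    times = np.array([result.summaries[i].bin_start_s for i in idx])
    class_names = sorted(set(labels.tolist()))
    sets = trainset.assemble(vectors, labels, times, class_names, n_per_class, seed=seed)
    bin_indices = np.array([result.summaries[i].bin_index for i in idx])
    return sets, class_names, bin_indices


def train_and_evaluate(
    sets: dict[str, trainset.TrainingSet],
    class_names: list[str],
    batch_size: int,
    seed: int = 0,
    max_epochs: int = 15,
) -> tuple[classifier.TrainedModel, list[dict], evaluation.ConfusionMatrix]:
    """Train the standard network on a split and score the test set."""
    spec = classifier.ModelSpec(input_dim=sets["train"].X.shape[1], n_classes=len(class_names))
    cfg = classifier.TrainConfig(batch_size=batch_size, max_epochs=max_epochs, seed=seed)
    model, history = classifier.train(
        spec, cfg, sets["train"].X, sets["train"].y, sets["val"].X, sets["val"].y, class_names
    )
    preds = classifier.predict(model, sets["test"].X)
    cm = evaluation.confusion(
        [class_names[i] for i in sets["test"].y],
        [class_names[i] for i in preds.labels],
        class_names,
    )
    return model, history, cm
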