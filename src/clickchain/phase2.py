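"""Phase-2 clustering: dataset-wide signal classes from bin summaries.

Bin-level cluster summaries from phase 1 are compared on their mean
spectra and mean waveform envelopes (IDI histograms are deliberately left
out of the similarity — they encourage duplicate classes — but are carried
through for the bin-level classifier inputs). The summary graph is pruned
to its strongest edges, Chinese Whispers is run with several seeds, the
consensus-most partition selected, weakly connected members dropped, and
each surviving cluster becomes a candidate signal class (template) for an
analyst to name. Analyst labels are then propagated down to every member
detection of every member summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clustering
from .clustering import UNCLUSTERED
from .phase1 import BinClusterSummary

log = logging.getLogger(__name__)

UNLABELED = "unlabeled"


@dataclass
class Phase2Params:
    retain_fraction: float = 0.10
    min_phase2_size: int = 50  # member summaries required to keep a template
    weak_node_fraction: float = 0.10
    max_summaries: int = 30_000
    n_repeats: int = 5
    cw_max_iter: int = 25
    duplicate_threshold: float = 0.95  # review-report flag level
    minimize_consensus: bool = False
    seed: int = 0


@dataclass
class ClassTemplate:
    class_id: int
    label: str
    member_summary_idx: np.ndarray  # indices into the input summary list
    mean_spectrum: np.ndarray
    mean_envelope: np.ndarray
    mean_idi_hist: np.ndarray

    @property
    def n_members(self) -> int:
        return len(self.member_summary_idx)


def bin_similarity(a: BinClusterSummary, b: BinClusterSummary) -> float:
    """Mean of the clipped spectrum and envelope correlations, in [0, 1]."""
    g = clustering.correlation_similarity(np.vstack([a.mean_spectrum, b.mean_spectrum]))
    s_spec = g.weights[0, 1] if not g.is_sparse else g.to_csr()[0, 1]
    g = clustering.correlation_similarity(np.vstack([a.mean_envelope, b.mean_envelope]))
    s_env = g.weights[0, 1] if not g.is_sparse else g.to_csr()[0, 1]
    return float((s_spec + s_env) / 2)


def summary_graph(summaries: list[BinClusterSummary]) -> clustering.SimilarityGraph:
    """Dense similarity graph over summaries (spectrum/envelope average)."""
    spec = np.vstack([s.mean_spectrum for s in summaries])
    env = np.vstack([s.mean_envelope for s in summaries])
    W = (clustering.correlation_similarity(spec).weights + clustering.correlation_similarity(env).weights) / 2
    return clustering.SimilarityGraph(W)


def cluster_summaries(
    summaries: list[BinClusterSummary], params: Phase2Params | None = None
) -> tuple[clustering.Partition, list[ClassTemplate], list[tuple[int, int, float]]]:
    """Cluster summaries into candidate classes.

    Returns (partition over the summaries, templates, duplicate report).
    The duplicate report lists template pairs whose mean features are more
    similar than ``duplicate_threshold`` — candidates for an analyst to
    merge under one name.
    """
    params = params or Phase2Params()
    n = len(summaries)
    if n < 2:
        return clustering.Partition(np.full(n, UNCLUSTERED)), [], []
    rng = np.random.default_rng(params.seed)
    keep = clustering.subsample_nodes(np.arange(n), params.max_summaries, rng)
    subset = [summaries[i] for i in keep]
    graph = summary_graph(subset)
    pruned = clustering.prune_edges(graph, params.retain_fraction)
    repeats = [
        clustering.chinese_whispers(pruned, max_iter=params.cw_max_iter, seed=int(rng.integers(2**31)))
        for _ in range(params.n_repeats)
    ]
    best = clustering.select_best_partition(repeats, minimize_consensus=params.minimize_consensus)
    best = clustering.prune_weak_nodes(pruned, best, params.weak_node_fraction)

    labels = np.full(n, UNCLUSTERED)
    labels[keep] = best.labels
    templates: list[ClassTemplate] = []
    for lab, rows in clustering.Partition(labels).members().items():
        if len(rows) < params.min_phase2_size:
            labels[rows] = UNCLUSTERED
            continue
        templates.append(
            ClassTemplate(
                class_id=len(templates),
                label=UNLABELED,
                member_summary_idx=rows,
                mean_spectrum=np.vstack([summaries[i].mean_spectrum for i in rows]).mean(axis=0),
                mean_envelope=np.vstack([summaries[i].mean_envelope for i in rows]).mean(axis=0),
                mean_idi_hist=np.vstack([summaries[i].idi_hist for i in rows]).mean(axis=0),
            )
        )
    if not templates:
        log.warning("no phase-2 cluster reached %d members", params.min_phase2_size)
    dup_report = []
    for i in range(len(templates)):
        for j in range(i + 1, len(templates)):
            a, b = templates[i], templates[j]
            sim = bin_similarity(
                BinClusterSummary(0, 0, 0, a.mean_spectrum, a.mean_envelope, a.mean_idi_hist, 0, np.empty(0)),
                BinClusterSummary(0, 0, 0, b.mean_spectrum, b.mean_envelope, b.mean_idi_hist, 0, np.empty(0)),
            )
            if sim >= params.duplicate_threshold:
                dup_report.append((a.class_id, b.class_id, sim))
    return clustering.Partition(labels), templates, dup_report


def assign_labels(
    templates: list[ClassTemplate],
    summaries: list[BinClusterSummary],
    label_map: dict[int, str] | None = None,
) -> tuple[list[ClassTemplate], pd.DataFrame]:
    """Attach analyst names and propagate them to member detections.

    ``label_map`` maps template class_id → name; several templates may map
    to the same name (they merge into one class). Unmapped templates keep
    the "unlabeled" name but are retained. Returns the labeled templates
    and a DataFrame (detection id, label, class_id, bin_index).
    """
    label_map = label_map or {}
    rows = []
    for t in templates:
        t.label = label_map.get(t.class_id, UNLABELED)
        for si in t.member_summary_idx:
            s = summaries[si]
            for det_id in s.member_ids:
                rows.append((det_id, t.label, t.class_id, s.bin_index))
    prop = pd.DataFrame(rows, columns=["id", "label", "class_id", "bin_index"])
    return templates, prop


def write_review_images(templates: list[ClassTemplate], summaries: list[BinClusterSummary], out_dir) -> list:
    """Concatenated-spectra PNG per template for analyst review."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in templates:
        spec = np.vstack([summaries[i].mean_spectrum for i in t.member_summary_idx])
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(spec.T, aspect="auto", origin="lower", cmap="viridis")
        ax.set_xlabel("member summary")
        ax.set_ylabel("spectrum bin")
        ax.set_title(f"class {t.class_id} ({t.label}), {t.n_members} summaries")
        p = out_dir / f"template_{t.class_id:02d}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
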