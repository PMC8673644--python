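"""Phase-1 clustering: per-time-bin class discovery and summarization.

Detections are grouped into fixed time bins (default 5 min). Within each
sufficiently occupied bin (default ≥ 50 detections), spectra are compared
pairwise, near-duplicates merged, the graph pruned to its strongest edges
and partitioned with Chinese Whispers. Each surviving cluster (default
≥ 50 members) is summarized by its mean spectrum, mean waveform envelope
and inter-detection-interval (IDI) histogram — the condensed, less noisy
description that the second clustering phase and the bin-level classifier
operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clustering
from .clustering import UNCLUSTERED

log = logging.getLogger(__name__)

IDI_EDGES = np.round(np.arange(0, 1.0 + 0.01 / 2, 0.01), 10)  # 0..1 s, 10-ms bins


@dataclass
class Phase1Params:
    bin_duration: float = 300.0
    min_bin_count: int = 50  # detections required before a bin is clustered
    min_cluster_size: int = 50  # detections required to keep a cluster
    retain_fraction: float = 0.10  # strongest edges kept for clustering
    dup_threshold: float = 0.98
    max_nodes: int = 10_000  # random subsample cap per bin
    cw_max_iter: int = 25
    use_envelope: bool = False  # compare on spectra by default
    seed: int = 0


@dataclass
class TimeBin:
    index: int
    start_s: float
    duration_s: float
    member_ids: np.ndarray


@dataclass
class BinClusterSummary:
    """One phase-1 cluster: normalized mean features + IDI histogram."""

    bin_index: int
    bin_start_s: float
    cluster_id: int
    mean_spectrum: np.ndarray  # min-max normalized to [0, 1]
    mean_envelope: np.ndarray  # min-max normalized to [0, 1]
    idi_hist: np.ndarray  # sums to 1 (all-zero when < 2 members)
    n_members: int
    member_ids: np.ndarray


def assign_bins(table: pd.DataFrame, bin_duration: float = 300.0) -> list[TimeBin]:
    """Partition detections into half-open time bins; empty bins omitted."""
    if len(table) == 0:
        return []
    idx = np.floor(table["time_s"].to_numpy() / bin_duration).astype(int)
    bins = []
    for b in np.unique(idx):
        ids = table["id"].to_numpy()[idx == b]
        bins.append(TimeBin(int(b), b * bin_duration, bin_duration, ids))
    return bins


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def summarize_cluster(
    times: np.ndarray,
    spectra: np.ndarray,
    envelopes: np.ndarray,
    member_ids: np.ndarray,
    bin_index: int = 0,
    bin_start_s: float = 0.0,
    cluster_id: int = 0,
    idi_edges: np.ndarray = IDI_EDGES,
) -> BinClusterSummary:
    """Mean features of one cluster.

    Spectra are averaged in the dB domain, envelopes linearly; both are
    min-max normalized to [0, 1]. IDIs are successive differences of the
    sorted member times, histogrammed on fixed edges and normalized to
    unit mass.
    """
    mean_spec = _minmax(spectra.mean(axis=0))
    mean_env = _minmax(envelopes.mean(axis=0))
    idi = np.diff(np.sort(np.asarray(times, dtype=float)))
    hist, _ = np.histogram(idi, bins=idi_edges)
    total = hist.sum()
    idi_hist = hist / total if total > 0 else hist.astype(float)
    return BinClusterSummary(
        bin_index=bin_index,
        bin_start_s=bin_start_s,
        cluster_id=cluster_id,
        mean_spectrum=mean_spec,
        mean_envelope=mean_env,
        idi_hist=idi_hist,
        n_members=len(member_ids),
        member_ids=np.asarray(member_ids),
    )


def cluster_bin(
    tbin: TimeBin,
    table: pd.DataFrame,
    arrays: dict[str, np.ndarray],
    params: Phase1Params,
    rng: np.random.Generator | None = None,
) -> list[BinClusterSummary]:
    """Discover and summarize the signal classes present in one bin.

    Pipeline: subsample (cap ``max_nodes``) → correlation similarity on
    spectra → merge near-duplicates → retain strongest edges → Chinese
    Whispers → drop clusters below ``min_cluster_size`` → summarize.
    May return an empty list when nothing coheres.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + tbin.index)
    if len(tbin.member_ids) < params.min_bin_count:
        log.info("bin %d skipped: %d < %d detections", tbin.index, len(tbin.member_ids), params.min_bin_count)
        return []
    ids = clustering.subsample_nodes(tbin.member_ids, params.max_nodes, rng)
    id_to_row = pd.Series(np.arange(len(table)), index=table["id"].to_numpy())
    rows = id_to_row.loc[ids].to_numpy()
    feats = arrays["spectrum"][rows]
    if params.use_envelope:
        feats = np.hstack([feats, arrays["envelope"][rows]])
    graph = clustering.correlation_similarity(feats, node_ids=ids)
    reduced, rep_members = clustering.merge_near_duplicates(graph, params.dup_threshold)
    pruned = clustering.prune_edges(reduced, params.retain_fraction)
    part = clustering.chinese_whispers(pruned, max_iter=params.cw_max_iter, seed=rng)

    # expand representative labels back to the original subsampled nodes
    full_labels = np.full(len(ids), UNCLUSTERED)
    for rep_row, members in rep_members.items():
        full_labels[members] = part.labels[rep_row]

    summaries = []
    times = table["time_s"].to_numpy()
    next_cluster = 0
    for lab in sorted(set(full_labels.tolist()) - {UNCLUSTERED}):
        sel = np.flatnonzero(full_labels == lab)
        if len(sel) < params.min_cluster_size:
            continue
        member_ids = ids[sel]
        member_rows = id_to_row.loc[member_ids].to_numpy()
        summaries.append(
            summarize_cluster(
                times[member_rows],
                arrays["spectrum"][member_rows],
                arrays["envelope"][member_rows],
                member_ids,
                bin_index=tbin.index,
                bin_start_s=tbin.start_s,
                cluster_id=next_cluster,
            )
        )
        next_cluster += 1
    return summaries


def run_phase1(
    table: pd.DataFrame, arrays: dict[str, np.ndarray], params: Phase1Params | None = None
) -> list[BinClusterSummary]:
    """Apply per-bin clustering over a whole detection table."""
    params = params or Phase1Params()
    out: list[BinClusterSummary] = []
    for tbin in assign_bins(table, params.bin_duration):
        out.extend(cluster_bin(tbin, table, arrays, params))
    return out
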