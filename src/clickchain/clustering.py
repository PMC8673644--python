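"""Graph clustering primitives shared by both clustering phases.

Events are compared with a correlation similarity (Pearson r clipped to
[0, 1]) — cheap, shape-sensitive and insensitive to amplitude offsets.
The resulting weighted network is sparsified by keeping only the strongest
few percent of edges, then partitioned by Chinese Whispers: a randomized
label-propagation scheme that begins with every node in its own cluster
and repeatedly reassigns each node to the label carrying the largest
summed edge weight among its neighbours, so the number of clusters is
discovered rather than specified.

Partitions are compared with normalized mutual information (NMI); when
clustering is repeated with several seeds the consensus-most partition
(minimum mean 1−NMI against the other repeats) is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import normalized_mutual_info_score

UNCLUSTERED = -1


@dataclass
class SimilarityGraph:
    """Symmetric weighted graph over ``n_nodes`` events.

    ``weights`` is dense (n, n) or CSR sparse, symmetric with zero
    diagonal; ``node_ids`` maps rows back to payload identifiers.
    """

    weights: np.ndarray | sparse.csr_matrix
    node_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.node_ids is None:
            self.node_ids = np.arange(self.n_nodes)
        self.node_ids = np.asarray(self.node_ids)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def is_sparse(self) -> bool:
        return sparse.issparse(self.weights)

    def to_csr(self) -> sparse.csr_matrix:
        return self.weights.tocsr() if self.is_sparse else sparse.csr_matrix(self.weights)

    def edge_list(self) -> list[tuple[int, int, float]]:
        w = self.to_csr().tocoo()
        return [(int(i), int(j), float(v)) for i, j, v in zip(w.row, w.col, w.data) if i < j]


@dataclass
class Partition:
    """Cluster labels per node; ``UNCLUSTERED`` marks removed nodes."""

    labels: np.ndarray
    node_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.node_ids is None:
            self.node_ids = np.arange(len(self.labels))
        self.node_ids = np.asarray(self.node_ids)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels != UNCLUSTERED].tolist()))

    def members(self) -> dict[int, np.ndarray]:
        out: dict[int, np.ndarray] = {}
        for lab in sorted(set(self.labels.tolist()) - {UNCLUSTERED}):
            out[lab] = np.flatnonzero(self.labels == lab)
        return out

    def canonical(self) -> np.ndarray:
        """Labels renumbered 0..K−1 in order of first appearance."""
        out = np.full(len(self.labels), UNCLUSTERED)
        mapping: dict[int, int] = {}
        for i, lab in enumerate(self.labels):
            if lab == UNCLUSTERED:
                continue
            out[i] = mapping.setdefault(int(lab), len(mapping))
        return out


def correlation_similarity(features: np.ndarray, node_ids=None) -> SimilarityGraph:
    """Pairwise Pearson r between feature rows, clipped to [0, 1].

    Anticorrelated shapes carry no attraction (negative r clips to 0).
    Zero-variance rows get zero similarity to everything, with a warning.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 rows")
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance rows get zero similarity")
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(degenerate, 1.0, sd * np.sqrt(X.shape[1]))
    Xn = Xc / denom[:, None]
    W = Xn @ Xn.T
    W[degenerate, :] = 0.0
    W[:, degenerate] = 0.0
    np.clip(W, 0.0, 1.0, out=W)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2
    return SimilarityGraph(W, node_ids)


def prune_edges(graph: SimilarityGraph, retain_fraction: float) -> SimilarityGraph:
    """Keep the globally strongest ``retain_fraction`` of off-diagonal weights.

    Ties at the cutoff weight are all kept. Nodes may end up isolated;
    Chinese Whispers leaves them as singletons.
    """
    if not (0 < retain_fraction <= 1):
        raise ValueError("retain_fraction must be in (0, 1]")
    if retain_fraction == 1.0:
        return SimilarityGraph(graph.weights.copy(), graph.node_ids)
    if graph.is_sparse:
        coo = graph.weights.tocoo()
        mask = coo.row < coo.col
        vals = coo.data[mask]
    else:
        iu = np.triu_indices(graph.n_nodes, k=1)
        vals = graph.weights[iu]
    pos = vals[vals > 0]
    if len(pos) == 0:
        return SimilarityGraph(sparse.csr_matrix((graph.n_nodes, graph.n_nodes)), graph.node_ids)
    n_keep = max(int(np.ceil(retain_fraction * len(vals))), 1)
    if n_keep >= len(vals):
        cutoff = vals.min()
    else:
        cutoff = np.partition(vals, len(vals) - n_keep)[len(vals) - n_keep]
    cutoff = max(cutoff, np.nextafter(0.0, 1.0))  # never keep zero-weight edges
    if graph.is_sparse:
        W = graph.weights.tocsr().copy()
        W.data[W.data < cutoff] = 0.0
        W.eliminate_zeros()
    else:
        W = sparse.csr_matrix(np.where(graph.weights >= cutoff, graph.weights, 0.0))
    return SimilarityGraph(W, graph.node_ids)


def merge_near_duplicates(
    graph: SimilarityGraph, dup_threshold: float = 0.98
) -> tuple[SimilarityGraph, dict[int, np.ndarray]]:
    """Collapse near-identical events to one representative each.

    Groups are transitive closures of the relation weight ≥ threshold
    (connected components). Returns the reduced graph over representatives
    and a map representative-row → original member rows.
    """
    W = graph.to_csr()
    high = W >= dup_threshold
    n_comp, comp = connected_components(high, directed=False)
    reps, members = [], {}
    for c in range(n_comp):
        rows = np.flatnonzero(comp == c)
        reps.append(int(rows[0]))
        members[len(reps) - 1] = rows
    reps = np.asarray(reps)
    if len(reps) == graph.n_nodes:
        return SimilarityGraph(graph.weights.copy(), graph.node_ids), {
            i: np.array([i]) for i in range(graph.n_nodes)
        }
    if graph.is_sparse:
        Wr = W[reps][:, reps]
    else:
        Wr = graph.weights[np.ix_(reps, reps)].copy()
        np.fill_diagonal(Wr, 0.0)
    return SimilarityGraph(Wr, graph.node_ids[reps]), members


def subsample_nodes(node_ids: np.ndarray, max_n: int, rng: np.random.Generator | int) -> np.ndarray:
    """Uniform random subset of size ``max_n`` when the pool exceeds it."""
    node_ids = np.asarray(node_ids)
    if len(node_ids) <= max_n:
        return node_ids
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    idx = rng.choice(len(node_ids), size=max_n, replace=False)
    return node_ids[np.sort(idx)]


def chinese_whispers(
    graph: SimilarityGraph, max_iter: int = 25, seed: int | np.random.Generator = 0
) -> Partition:
    """Randomized label propagation until reassignments cease.

    Every node starts with a unique label. Each iteration visits the nodes
    in a fresh seeded random order; each node adopts the label with the
    largest summed edge weight among its neighbours, ties broken by seeded
    random choice. Isolated nodes keep their singleton labels.
    """
    n = graph.n_nodes
    if n == 0:
        return Partition(np.empty(0, dtype=int), graph.node_ids)
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    W = graph.to_csr()
    indptr, indices, data = W.indptr, W.indices, W.data
    labels = np.arange(n)
    for _ in range(max_iter):
        changed = 0
        for node in rng.permutation(n):
            lo, hi = indptr[node], indptr[node + 1]
            if hi == lo:
                continue
            nbr_labels = labels[indices[lo:hi]]
            strength = np.bincount(nbr_labels, weights=data[lo:hi])
            best = strength.max()
            cands = np.flatnonzero(strength == best)
            new = int(cands[0] if len(cands) == 1 else rng.choice(cands))
            if new != labels[node]:
                labels[node] = new
                changed += 1
        if changed == 0:
            break
    return Partition(labels, graph.node_ids)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(p: Partition | np.ndarray, q: Partition | np.ndarray) -> float:
    """NMI = 2·I(p;q)/(H(p)+H(q)) ∈ [0, 1].

    Convention for degenerate cases: two single-cluster partitions are
    identical (1.0); a single-cluster partition against a multi-cluster one
    carries zero information (0.0).
    """
    lp = p.canonical() if isinstance(p, Partition) else np.asarray(p)
    lq = q.canonical() if isinstance(q, Partition) else np.asarray(q)
    if len(lp) != len(lq):
        raise ValueError("partitions cover different node sets")
    hp = _entropy(np.bincount(lp - lp.min()))
    hq = _entropy(np.bincount(lq - lq.min()))
    if hp == 0 and hq == 0:
        return 1.0
    if hp == 0 or hq == 0:
        return 0.0
    return float(normalized_mutual_info_score(lp, lq, average_method="arithmetic"))


def select_best_partition(partitions: list[Partition], minimize_consensus: bool = False) -> Partition:
    """Pick the consensus-most of several clustering repeats.

    Default: minimize the mean (1 − NMI) against the other candidates,
    i.e. return the repeat most similar to the rest. ``minimize_consensus``
    flips the direction (select the outlier) for the literal reading of
    the selection rule.
    """
    if not partitions:
        raise ValueError("no partitions given")
    if len(partitions) == 1:
        return partitions[0]
    k = len(partitions)
    nmi = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            nmi[i, j] = nmi[j, i] = normalized_mutual_information(partitions[i], partitions[j])
    score = (1.0 - nmi).sum(axis=1) / (k - 1)
    idx = int(np.argmax(score)) if minimize_consensus else int(np.argmin(score))
    return partitions[idx]


def prune_weak_nodes(graph: SimilarityGraph, partition: Partition, fraction: float) -> Partition:
    """Mark the most weakly connected ``fraction`` of each cluster unclustered.

    Strength is the summed within-cluster edge weight. The number removed
    per cluster is ceil(fraction·size) capped at size − 1, so singletons
    are kept.
    """
    if fraction < 0 or fraction >= 1:
        raise ValueError("fraction must be in [0, 1)")
    labels = partition.labels.copy()
    if fraction == 0:
        return Partition(labels, partition.node_ids)
    W = graph.to_csr()
    for lab, rows in partition.members().items():
        if len(rows) < 2:
            continue
        sub = W[rows][:, rows]
        strength = np.asarray(sub.sum(axis=1)).ravel()
        n_remove = min(int(np.ceil(fraction * len(rows))), len(rows) - 1)
        weakest = rows[np.argsort(strength, kind="stable")[:n_remove]]
        labels[weakest] = UNCLUSTERED
    return Partition(labels, partition.node_ids)
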