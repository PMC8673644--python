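"""Classifier evaluation: confusion, precision/recall, threshold sweeps.

Conventions: confusion cell (p, t) counts items predicted p with true
class t — rows are predictions, columns truth. Precision is diagonal over
row sum (per predicted class), recall diagonal over column sum (per true
class). In a probability-threshold sweep, items whose confidence falls
below the threshold are discarded: they count against recall but not
against precision; precision with zero retained items is undefined (NaN).

Bin-level accounting adds a "none" prediction row: a class truly present
in a time bin that received no cluster or label in that bin is counted as
predicted-"none", and accuracy is reported both including and excluding
that row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NONE_LABEL = "none"


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray  # (pred, true)
    mode: str = "counts"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else np.nan

    def precision(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    def recall(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, np.diag(self.counts) / col, np.nan)

    def as_percent(self) -> "ConfusionMatrix":
        total = self.counts.sum()
        cells = 100.0 * self.counts / total if total else self.counts.astype(float)
        return ConfusionMatrix(self.classes, cells, mode="percent-of-total")


def confusion(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    classes: list[str],
    mode: str = "counts",
) -> ConfusionMatrix:
    """Count-based confusion matrix; ``mode="percent"`` normalizes to 100."""
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=float)
    for t, p in zip(true_labels, pred_labels):
        counts[index[p], index[t]] += 1
    cm = ConfusionMatrix(list(classes), counts)
    return cm.as_percent() if mode.startswith("percent") else cm


def pr_sweep(
    probabilities: np.ndarray,
    true_labels: np.ndarray,
    thresholds: np.ndarray,
) -> pd.DataFrame:
    """Per-class precision/recall retaining only confidences ≥ threshold.

    Returns a long DataFrame (threshold, class_index, precision, recall,
    n_retained). Recall denominators are the full per-class truth counts;
    precision over retained predictions only (NaN when none retained).
    """
    probabilities = np.asarray(probabilities)
    true_labels = np.asarray(true_labels)
    pred = probabilities.argmax(axis=1)
    score = probabilities.max(axis=1)
    n_classes = probabilities.shape[1]
    rows = []
    for tau in np.sort(np.asarray(thresholds, dtype=float)):
        kept = score >= tau
        for c in range(n_classes):
            pred_c = kept & (pred == c)
            true_c = true_labels == c
            tp = int((pred_c & true_c).sum())
            n_pred = int(pred_c.sum())
            n_true = int(true_c.sum())
            rows.append(
                (
                    tau,
                    c,
                    tp / n_pred if n_pred else np.nan,
                    tp / n_true if n_true else np.nan,
                    n_pred,
                )
            )
    return pd.DataFrame(rows, columns=["threshold", "class_index", "precision", "recall", "n_retained"])


def bin_level_align(
    bin_predictions: dict[int, list[str]],
    bin_truth: dict[int, list[str]],
    classes: list[str],
) -> ConfusionMatrix:
    """Match per-bin predicted labels against per-bin true classes.

    For each (bin, true class) pair: a prediction of that class in the bin
    is a diagonal cell; otherwise a leftover unmatched prediction in the
    bin becomes the confused cell; otherwise the pair counts as
    predicted-"none" (no cluster formed, or the cluster got no label).
    Total cell count equals the number of (bin, true class) pairs.
    """
    all_classes = list(classes) + [NONE_LABEL]
    index = {c: i for i, c in enumerate(all_classes)}
    counts = np.zeros((len(all_classes), len(all_classes)), dtype=float)
    for b, truths in bin_truth.items():
        preds = list(bin_predictions.get(b, []))
        unmatched = []
        for t in truths:
            if t in preds:
                preds.remove(t)
                counts[index[t], index[t]] += 1
            else:
                unmatched.append(t)
        for t in unmatched:
            if preds:
                p = preds.pop(0)
                counts[index[p], index[t]] += 1
            else:
                counts[index[NONE_LABEL], index[t]] += 1
    return ConfusionMatrix(all_classes, counts)


def accuracy_with_and_without_none(cm: ConfusionMatrix) -> tuple[float, float]:
    """(accuracy including the "none" row, accuracy excluding it)."""
    inc = cm.accuracy
    if NONE_LABEL not in cm.classes:
        return inc, inc
    i = cm.classes.index(NONE_LABEL)
    keep = [k for k in range(len(cm.classes)) if k != i]
    total = cm.counts[keep, :].sum()  # drop the "none" prediction row
    diag = sum(cm.counts[k, k] for k in keep)
    return inc, float(diag / total) if total else np.nan


def probability_histogram(
    probabilities: np.ndarray, edges: np.ndarray | None = None
) -> dict[int, np.ndarray]:
    """Per-predicted-class histogram of confidence scores."""
    probabilities = np.asarray(probabilities)
    if edges is None:
        edges = np.linspace(0, 1, 21)
    pred = probabilities.argmax(axis=1)
    score = probabilities.max(axis=1)
    out = {}
    for c in range(probabilities.shape[1]):
        hist, _ = np.histogram(np.clip(score[pred == c], edges[0], edges[-1]), bins=edges)
        out[c] = hist
    return out
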