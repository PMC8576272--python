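"""Residue-level evaluation: confusion-matrix metrics, ranking curves, splits.

Thresholded metrics are the classical five — accuracy, precision, recall,
F1 and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

computed exactly from integer counts; any metric whose denominator is zero
is reported as 0 with an explicit flag rather than NaN so cross-validation
aggregation stays stable.

AUROC is computed by the rank (Mann-Whitney) formulation with midrank
handling of ties, which equals the trapezoidal area under the ROC curve.
AUPRC is the step-wise (right-continuous) precision-recall sum, i.e.
average precision without linear interpolation.

Data splitting is always at the *protein* level — all residues of a
protein travel together — so a residue never shares a fold with its own
window neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .io_formats import ProteinRecord


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvaluationReport:
    """All residue-level metrics at one decision threshold."""

    counts: ConfusionCounts
    acc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: float
    auprc: float
    threshold: float
    zero_denominator: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def confusion(y: np.ndarray, scores: np.ndarray, threshold: float) -> ConfusionCounts:
    """Count TP/FP/TN/FN with the rule: predicted positive iff score >= threshold."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError(f"labels and scores lengths disagree: {y.shape} vs {scores.shape}")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be 0 or 1 (exclude missing labels upstream)")
    pred = scores >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, F1 and MCC from confusion counts.

    Returns the five metrics plus ``zero_denominator``, the list of metric
    names whose denominator vanished (those metrics are reported as 0).
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion table")
    flags: list[str] = []

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / total
    precision = ratio("precision", tp, tp + fp)
    recall = ratio("recall", tp, tp + fn)
    f1 = ratio("f1", 2 * precision * recall, precision + recall)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio("mcc", tp * tn - fp * fn, mcc_den)
    return {
        "acc": acc,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
        "zero_denominator": flags,
    }


def auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Ties receive midranks, so the value equals trapezoidal integration of
    the ROC curve and the pair-counting probability
    P(score_pos > score_neg) + 1/2 P(tie).
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores, method="average")
    rank_sum = float(np.sum(ranks[y == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc(y: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise area under the precision-recall curve (average precision).

    Sums precision * (increment in recall) over distinct score thresholds,
    descending; no linear interpolation of precision.  With constant scores
    this reduces to the positive prevalence.
    """
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = float(np.sum(y == 1))
    if n_pos == 0:
        raise ValueError("AUPRC undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    # only the last index of each tied-score group is a valid operating point
    last_of_group = np.append(s_sorted[1:] != s_sorted[:-1], True)
    tp = tp[last_of_group]
    fp = fp[last_of_group]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum(precision * (recall - recall_prev)))


def roc_curve_points(y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points at every distinct threshold, for export/plotting."""
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    last = np.append(s_sorted[1:] != s_sorted[:-1], True)
    n_pos, n_neg = tp[-1], fp[-1]
    fpr = np.concatenate([[0.0], fp[last] / max(n_neg, 1)])
    tpr = np.concatenate([[0.0], tp[last] / max(n_pos, 1)])
    return np.column_stack([fpr, tpr])


def pr_curve_points(y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(recall, precision) points at every distinct threshold."""
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    last = np.append(s_sorted[1:] != s_sorted[:-1], True)
    recall = tp[last] / max(tp[-1], 1)
    precision = tp[last] / (tp[last] + fp[last])
    return np.column_stack([recall, precision])


def evaluate(y: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> EvaluationReport:
    """Full report: confusion metrics at ``threshold`` plus AUROC and AUPRC."""
    counts = confusion(y, scores, threshold)
    m = classification_metrics(counts)
    return EvaluationReport(
        counts=counts,
        acc=m["acc"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        mcc=m["mcc"],
        auroc=auroc(y, scores),
        auprc=auprc(y, scores),
        threshold=threshold,
        zero_denominator=m["zero_denominator"],
    )


def best_f1_threshold(y: np.ndarray, scores: np.ndarray) -> float:
    """Threshold (a distinct score value) maximising F1; ties -> lowest threshold."""
    y = np.asarray(y)
    best_thr, best_f1 = 0.5, -1.0
    for thr in np.unique(scores):
        m = classification_metrics(confusion(y, scores, thr))
        if m["f1"] > best_f1 or (m["f1"] == best_f1 and thr < best_thr):
            best_thr, best_f1 = float(thr), m["f1"]
    return best_thr


def split_proteins(
    records: Sequence[ProteinRecord], fractions: dict[str, float], seed: int
) -> dict[str, list[ProteinRecord]]:
    """Random protein-level partition into named parts (e.g. train/test).

    Part sizes are the fractions rounded to whole proteins, the last part
    absorbing the remainder; the same seed reproduces the same partition.
    """
    names = list(fractions)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(records)
    if n < len(names):
        raise ValueError(f"cannot split {n} proteins into {len(names)} parts")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = [int(round(fractions[name] * n)) for name in names[:-1]]
    sizes.append(n - sum(sizes))
    if min(sizes) < 1:
        raise ValueError("a part would be empty; adjust fractions")
    parts: dict[str, list[ProteinRecord]] = {}
    start = 0
    for name, size in zip(names, sizes):
        parts[name] = [records[i] for i in perm[start : start + size]]
        start += size
    return parts


def kfold(
    records: Sequence[ProteinRecord], k: int, seed: int
) -> list[tuple[list[ProteinRecord], list[ProteinRecord]]]:
    """Protein-level k-fold: k (train, held-out) pairs, each protein held out once."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(records):
        raise ValueError(f"k={k} exceeds protein count {len(records)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        held = [records[j] for j in folds[i]]
        train = [records[j] for f in folds[:i] + folds[i + 1 :] for j in f]
        out.append((train, held))
    return out
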