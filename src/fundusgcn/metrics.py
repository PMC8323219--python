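"""Multi-label evaluation: micro/macro F1, per-class accuracy and AUC.

Micro ("overall") scores pool true/false positives across all classes before
forming precision and recall; macro ("per-class") scores average per-class
precision and recall first.  Both F1 values are the harmonic mean of their
precision/recall pair.  Per-class AUC uses the rank (Mann-Whitney)
formulation — the probability that a random positive outranks a random
negative, ties counted one half.

Conventions for edge cases, chosen to match common multi-label practice:
precision or recall with an empty denominator is 0; a class with no positives
or no negatives has an undefined AUC, reported as NaN and excluded from
summary means with a warning (never coerced to 0 or 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "micro_scores",
    "macro_scores",
    "per_class_accuracy",
    "per_class_auc",
    "evaluate_predictions",
]


@dataclass
class ConfusionCounts:
    """Per-class 2x2 tallies; each array has one entry per class."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.tp.size

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


@dataclass
class MetricReport:
    """The full evaluation suite for one prediction set."""

    op: float
    or_: float
    of1: float
    cp: float
    cr: float
    cf1: float
    labels: list[str] = field(default_factory=list)
    accuracy: np.ndarray = field(default_factory=lambda: np.zeros(0))
    auc: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_dict(self) -> dict:
        return {
            "OP": self.op, "OR": self.or_, "OF1": self.of1,
            "CP": self.cp, "CR": self.cr, "CF1": self.cf1,
            "per_class": {
                lab: {"Acc": float(a),
                      "AUC": None if np.isnan(u) else float(u)}
                for lab, a, u in zip(self.labels, self.accuracy, self.auc)
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_table(self) -> str:
        """Human-readable per-lesion Acc/AUC table plus the summary row."""
        width = max((len(lab) for lab in self.labels), default=5)
        lines = [f"{'Label'.ljust(width)}    Acc    AUC"]
        for lab, a, u in zip(self.labels, self.accuracy, self.auc):
            auc_str = "   --" if np.isnan(u) else f"{u:.3f}"
            lines.append(f"{lab.ljust(width)}  {a:.3f}  {auc_str}")
        lines.append("")
        lines.append(f"OF1 = {self.of1:.3f}  CF1 = {self.cf1:.3f}  "
                     f"(OP {self.op:.3f} / OR {self.or_:.3f}, "
                     f"CP {self.cp:.3f} / CR {self.cr:.3f})")
        return "\n".join(lines)


def _check_pair(y_true, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true)
    y_hat = np.asarray(y_hat)
    if y_true.shape != y_hat.shape:
        raise ValueError(
            f"shape mismatch: truth {y_true.shape} vs prediction "
            f"{y_hat.shape}")
    if y_true.ndim != 2:
        raise ValueError("expected n_samples x n_classes matrices")
    for name, arr in (("truth", y_true), ("prediction", y_hat)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} matrix must be binary")
    return y_true.astype(np.int64), y_hat.astype(np.int64)


def confusion_counts(y_true, y_hat) -> ConfusionCounts:
    """Per-class TP/FP/TN/FN over an n x N binary truth/prediction pair."""
    y_true, y_hat = _check_pair(y_true, y_hat)
    tp = ((y_true == 1) & (y_hat == 1)).sum(axis=0)
    fp = ((y_true == 0) & (y_hat == 1)).sum(axis=0)
    tn = ((y_true == 0) & (y_hat == 0)).sum(axis=0)
    fn = ((y_true == 1) & (y_hat == 0)).sum(axis=0)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _f1(p: float, r: float) -> float:
    return _safe_div(2.0 * p * r, p + r)


def micro_scores(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Overall precision, recall, F1 from globally pooled counts."""
    op = _safe_div(counts.tp.sum(), counts.tp.sum() + counts.fp.sum())
    orec = _safe_div(counts.tp.sum(), counts.tp.sum() + counts.fn.sum())
    return op, orec, _f1(op, orec)


def macro_scores(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Per-class precision/recall averaged over classes, then F1."""
    n = counts.n_classes
    cp = sum(_safe_div(tp, tp + fp)
             for tp, fp in zip(counts.tp, counts.fp)) / n
    cr = sum(_safe_div(tp, tp + fn)
             for tp, fn in zip(counts.tp, counts.fn)) / n
    return cp, cr, _f1(cp, cr)


def per_class_accuracy(counts: ConfusionCounts) -> np.ndarray:
    """(TP + TN) / n for every class."""
    total = counts.tp + counts.fp + counts.tn + counts.fn
    if np.any(total == 0):
        raise ValueError("accuracy undefined with zero samples")
    return (counts.tp + counts.tn) / total


def per_class_auc(scores, y_true) -> np.ndarray:
    """Rank-based AUC per class; NaN where a class lacks both outcomes.

    Computed as (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg) with R_pos the
    summed mid-ranks of the positives — the Mann-Whitney U statistic, which
    counts tied positive-negative pairs as one half.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape or scores.ndim != 2:
        raise ValueError("scores and truth must be matching n x N matrices")
    n, n_classes = scores.shape
    out = np.full(n_classes, np.nan)
    degenerate = []
    for j in range(n_classes):
        pos = y_true[:, j] == 1
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            degenerate.append(j)
            continue
        ranks = rankdata(scores[:, j])  # mid-ranks handle ties
        r_pos = ranks[pos].sum()
        out[j] = (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    if degenerate:
        warnings.warn(
            f"AUC undefined for classes {degenerate} (single outcome); "
            "reported as NaN and excluded from summaries", stacklevel=2)
    return out


def evaluate_predictions(y_true, y_hat, scores=None,
                         labels: list[str] | None = None) -> MetricReport:
    """Assemble the full report from truth, hard predictions and raw scores."""
    counts = confusion_counts(y_true, y_hat)
    op, orec, of1 = micro_scores(counts)
    cp, cr, cf1 = macro_scores(counts)
    acc = per_class_accuracy(counts)
    if scores is not None:
        auc = per_class_auc(scores, y_true)
    else:
        auc = np.full(counts.n_classes, np.nan)
    if labels is None:
        labels = [f"label_{i}" for i in range(counts.n_classes)]
    return MetricReport(op=op, or_=orec, of1=of1, cp=cp, cr=cr, cf1=cf1,
                        labels=list(labels), accuracy=acc, auc=auc)
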