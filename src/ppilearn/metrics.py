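"""Seven-indicator evaluation: Acc, Sn, Spe, Pre, F1, AUC and MCC.

All metrics are reported as fractions (AUC and MCC included); the CLI layer
formats them as percentages.  A metric whose denominator vanishes is
reported as ``None`` together with a human-readable reason, never as a
silent zero.  AUC is computed with the rank-sum (Mann-Whitney) statistic
using midranks for ties, which equals the trapezoidal area under the ROC
curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "auc_score",
    "compute_metrics",
    "mean_reports",
    "format_percent_table",
]

METRIC_ORDER = ("acc", "sn", "spe", "pre", "f1", "auc", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Metric values (fractions; ``None`` where undefined) plus counts."""

    acc: float | None
    sn: float | None
    spe: float | None
    pre: float | None
    f1: float | None
    auc: float | None
    mcc: float | None
    counts: ConfusionCounts
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            **{m: getattr(self, m) for m in METRIC_ORDER},
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "undefined": dict(self.undefined),
        }


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from 0/1 labels and 0/1 predictions."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {labels.shape[0]} labels vs {predictions.shape[0]} predictions"
        )
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """ROC area via the Mann-Whitney rank statistic with midranks for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one row of each class")
    ranks = rankdata(scores)
    pos_rank_sum = float(np.sum(ranks[labels == 1]))
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(
    counts: ConfusionCounts,
    scores: Sequence[float] | None = None,
    labels: Sequence[int] | None = None,
) -> MetricsReport:
    """Evaluate the seven indicators from confusion counts (+ scores for AUC).

    Acc = (TP+TN)/total, Sn = TP/(TP+FN), Spe = TN/(TN+FP),
    Pre = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN),
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero rows")
    undefined: dict[str, str] = {}

    acc = (counts.tp + counts.tn) / counts.total
    sn = _ratio(counts.tp, counts.tp + counts.fn)
    if sn is None:
        undefined["sn"] = "no actual positives (TP+FN=0)"
    spe = _ratio(counts.tn, counts.tn + counts.fp)
    if spe is None:
        undefined["spe"] = "no actual negatives (TN+FP=0)"
    pre = _ratio(counts.tp, counts.tp + counts.fp)
    if pre is None:
        undefined["pre"] = "no predicted positives (TP+FP=0)"
    f1_den = 2 * counts.tp + counts.fp + counts.fn
    f1 = 2 * counts.tp / f1_den if f1_den else None
    if f1 is None:
        undefined["f1"] = "no positives in labels or predictions"

    mcc_den = (
        (counts.tp + counts.fp)
        * (counts.tp + counts.fn)
        * (counts.tn + counts.fp)
        * (counts.tn + counts.fn)
    )
    if mcc_den:
        mcc = (counts.tp * counts.tn - counts.fp * counts.fn) / math.sqrt(mcc_den)
    else:
        mcc = None
        undefined["mcc"] = "a confusion-matrix margin is zero"

    auc: float | None = None
    if scores is not None and labels is not None:
        try:
            auc = auc_score(labels, scores)
        except ValueError as exc:
            undefined["auc"] = str(exc)
    else:
        undefined["auc"] = "scores not provided"

    return MetricsReport(
        acc=acc, sn=sn, spe=spe, pre=pre, f1=f1, auc=auc, mcc=mcc,
        counts=counts, undefined=undefined,
    )


def mean_reports(reports: Iterable[MetricsReport]) -> dict[str, float | None]:
    """Per-metric mean over folds, ignoring undefined entries."""
    reports = list(reports)
    out: dict[str, float | None] = {}
    for m in METRIC_ORDER:
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        out[m] = float(np.mean(vals)) if vals else None
    return out


def format_percent_table(reports: Iterable[MetricsReport]) -> str:
    """Fixed-width table (metrics as percentages, 2 decimals) per fold + mean."""
    reports = list(reports)
    header = ["fold"] + [m.upper() for m in METRIC_ORDER]
    lines = ["\t".join(header)]

    def fmt(v: float | None) -> str:
        return f"{100.0 * v:.2f}" if v is not None else "NA"

    for i, r in enumerate(reports, 1):
        lines.append("\t".join([str(i)] + [fmt(getattr(r, m)) for m in METRIC_ORDER]))
    means = mean_reports(reports)
    lines.append("\t".join(["mean"] + [fmt(means[m]) for m in METRIC_ORDER]))
    return "\n".join(lines)
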