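"""Segmentation evaluation: Dice, Jaccard, Recall, Accuracy, VOE.

All metrics are computed from the pixel confusion counts with foreground as
the positive class.  VOE is the volumetric overlap error ``1 - Jaccard``,
and Dice and Jaccard are tied by ``Dice = 2J / (1 + J)``.  Accuracy is the
standard overall pixel accuracy ``(TP + TN) / total``.  Degenerate cases are
fixed conventions: when prediction and ground truth are both empty, Dice and
Jaccard are 1 (VOE 0); Recall is 1 whenever the ground truth is empty, and
in particular whenever the prediction covers the whole ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvaluationRecord:
    """Metric values on [0, 1]; multiply by 100 to report percentages."""

    dice: float
    jaccard: float
    recall: float
    accuracy: float
    voe: float


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts between two aligned binary masks."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(tp=int((p & g).sum()), fp=int((p & ~g).sum()),
                           fn=int((~p & g).sum()), tn=int((~p & ~g).sum()))


def evaluate(pred: np.ndarray, gt: np.ndarray) -> EvaluationRecord:
    """All five metrics for one mask pair."""
    c = confusion(pred, gt)
    inter = c.tp
    union = c.tp + c.fp + c.fn
    pred_v = c.tp + c.fp
    gt_v = c.tp + c.fn
    jaccard = 1.0 if union == 0 else inter / union
    dice = 1.0 if pred_v + gt_v == 0 else 2.0 * inter / (pred_v + gt_v)
    recall = 1.0 if gt_v == 0 else c.tp / gt_v
    accuracy = (c.tp + c.tn) / c.total
    return EvaluationRecord(dice=dice, jaccard=jaccard, recall=recall,
                            accuracy=accuracy, voe=1.0 - jaccard)


@dataclass
class AggregateReport:
    per_class: dict[int, EvaluationRecord]
    overall: EvaluationRecord


def _mean_record(records) -> EvaluationRecord:
    return EvaluationRecord(**{
        f.name: float(np.mean([getattr(r, f.name) for r in records]))
        for f in fields(EvaluationRecord)})


def aggregate(records: list[tuple[int, EvaluationRecord]]) -> AggregateReport:
    """Unweighted per-class means plus the overall mean over all images."""
    if not records:
        raise ValueError("no records to aggregate")
    by_class: dict[int, list[EvaluationRecord]] = {}
    for cid, rec in records:
        by_class.setdefault(cid, []).append(rec)
    return AggregateReport(
        per_class={cid: _mean_record(v) for cid, v in sorted(by_class.items())},
        overall=_mean_record([rec for _, rec in records]))


def write_records_csv(records: list[tuple[str, int, EvaluationRecord]],
                      path) -> None:
    """Per-image CSV: file, class, dice, jaccard, recall, accuracy, voe."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["file", "class", "dice", "jaccard", "recall",
                    "accuracy", "voe"])
        for name, cid, r in records:
            w.writerow([name, cid, r.dice, r.jaccard, r.recall,
                        r.accuracy, r.voe])


def write_aggregate_csv(report: AggregateReport, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "dice", "jaccard", "recall", "accuracy", "voe"])
        for cid, r in report.per_class.items():
            w.writerow([cid, r.dice, r.jaccard, r.recall, r.accuracy, r.voe])
        o = report.overall
        w.writerow(["overall", o.dice, o.jaccard, o.recall, o.accuracy, o.voe])
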