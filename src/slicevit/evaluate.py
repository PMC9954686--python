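"""Slice- and subject-level classification reports, vote-for-majority
aggregation, repetition summaries and normalized confusion matrices."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .train import SlicePrediction

__all__ = [
    "SubjectPrediction",
    "EvalReport",
    "RepetitionSummary",
    "vote_majority",
    "classification_report",
    "aggregate_repetitions",
    "normalized_confusion",
]


@dataclass(frozen=True)
class SubjectPrediction:
    """Vote-for-majority aggregate of one subject's slice predictions."""

    subject_id: str
    true_label: str
    class_vote_fractions: dict[str, float]
    predicted_label: str


@dataclass
class EvalReport:
    """Per-class and averaged precision/recall/F1 plus accuracy."""

    per_class: dict[str, dict[str, float]]
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    accuracy: float
    support: dict[str, int]
    level: str = "slice"

    def metric(self, name: str, average: str = "weighted") -> float:
        if name == "accuracy":
            return self.accuracy
        return {"macro": self.macro_avg, "weighted": self.weighted_avg}[average][name]

    def to_frame(self) -> pd.DataFrame:
        rows = {label: dict(vals, support=self.support[label])
                for label, vals in self.per_class.items()}
        rows["macro avg"] = dict(self.macro_avg, support=sum(self.support.values()))
        rows["weighted avg"] = dict(self.weighted_avg, support=sum(self.support.values()))
        frame = pd.DataFrame(rows).T
        frame.loc["accuracy"] = {"precision": np.nan, "recall": np.nan,
                                 "f1": self.accuracy,
                                 "support": sum(self.support.values())}
        return frame


def vote_majority(slice_preds: list[SlicePrediction],
                  use_probabilities: bool = False) -> list[SubjectPrediction]:
    """Aggregate slice predictions per subject id.

    By default each subject's vote fractions count the predicted hard
    labels of its slices; ``use_probabilities`` averages the softmax
    probability vectors instead. Argmax ties break toward the
    lexicographically smallest class label.
    """
    if not slice_preds:
        raise ValueError("no slice predictions to aggregate")
    by_subject: dict[str, list[SlicePrediction]] = {}
    for pred in slice_preds:
        by_subject.setdefault(pred.subject_id, []).append(pred)
    out: list[SubjectPrediction] = []
    for subject_id in sorted(by_subject):
        preds = by_subject[subject_id]
        labels = preds[0].labels
        if use_probabilities:
            mean_probs = np.mean([p.probabilities for p in preds], axis=0)
            fractions = {lab: float(v) for lab, v in zip(labels, mean_probs)}
        else:
            counts = Counter(p.predicted_label for p in preds)
            total = len(preds)
            fractions = {lab: counts.get(lab, 0) / total for lab in labels}
        winner = max(sorted(fractions), key=lambda lab: fractions[lab])
        true_labels = {p.true_label for p in preds}
        if len(true_labels) != 1:
            raise ValueError(f"subject {subject_id} has inconsistent true labels")
        out.append(SubjectPrediction(subject_id=subject_id,
                                     true_label=preds[0].true_label,
                                     class_vote_fractions=fractions,
                                     predicted_label=winner))
    return out


def _as_labels(preds, trues) -> tuple[list, list]:
    preds, trues = list(preds), list(trues)
    if len(preds) != len(trues):
        raise ValueError("prediction and truth sequences differ in length")
    if not preds:
        raise ValueError("empty label sequences")
    return preds, trues


def classification_report(pred_labels, true_labels, level: str = "slice",
                          labels: list | None = None) -> EvalReport:
    """Standard report: per-class precision/recall/F1 with macro and
    support-weighted averages; never-predicted classes get precision 0."""
    preds, trues = _as_labels(pred_labels, true_labels)
    if labels is None:
        labels = sorted(set(trues) | set(preds))
    per_class: dict[str, dict[str, float]] = {}
    support: dict[str, int] = {}
    for lab in labels:
        tp = sum(1 for p, t in zip(preds, trues) if p == lab and t == lab)
        fp = sum(1 for p, t in zip(preds, trues) if p == lab and t != lab)
        fn = sum(1 for p, t in zip(preds, trues) if p != lab and t == lab)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[lab] = {"precision": precision, "recall": recall, "f1": f1}
        support[lab] = sum(1 for t in trues if t == lab)
    n = len(trues)
    macro = {m: float(np.mean([per_class[lab][m] for lab in labels]))
             for m in ("precision", "recall", "f1")}
    weighted = {m: sum(per_class[lab][m] * support[lab] for lab in labels) / n
                for m in ("precision", "recall", "f1")}
    accuracy = sum(1 for p, t in zip(preds, trues) if p == t) / n
    return EvalReport(per_class=per_class, macro_avg=macro, weighted_avg=weighted,
                      accuracy=accuracy, support=support, level=level)


def subject_report(subject_preds: list[SubjectPrediction], level: str = "subject") -> EvalReport:
    return classification_report([p.predicted_label for p in subject_preds],
                                 [p.true_label for p in subject_preds], level=level)


@dataclass
class RepetitionSummary:
    """mean +/- std (population) of each metric over repeated runs."""

    means: dict[str, float]
    stds: dict[str, float]
    n_repetitions: int
    level: str

    def render(self, metric: str, decimals: int = 2) -> str:
        m = round(self.means[metric], decimals)
        s = round(self.stds[metric], decimals)
        fmt = lambda v: f"{v:g}"
        return f"{fmt(m)} ± {fmt(s)}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "std": self.stds})


_SUMMARY_METRICS = ("precision", "recall", "f1", "accuracy")


def aggregate_repetitions(reports: list[EvalReport], average: str = "weighted",
                          ddof: int = 0) -> RepetitionSummary:
    """Aggregate repeated runs as mean and (population) std per metric."""
    if not reports:
        raise ValueError("no reports to aggregate")
    levels = {r.level for r in reports}
    if len(levels) != 1:
        raise ValueError(f"cannot aggregate mixed levels {sorted(levels)}")
    means, stds = {}, {}
    for metric in _SUMMARY_METRICS:
        values = np.array([r.metric(metric, average) for r in reports], dtype=float)
        means[metric] = float(values.mean())
        stds[metric] = float(values.std(ddof=ddof)) if len(values) > 1 else 0.0
    return RepetitionSummary(means=means, stds=stds, n_repetitions=len(reports),
                             level=levels.pop())


def normalized_confusion(pred_labels, true_labels,
                         labels: list | None = None) -> pd.DataFrame:
    """Row r, column c = fraction of true-class-r items predicted as c.

    Rows of nonempty true classes sum to 1; an empty true class yields an
    all-zero row.
    """
    preds, trues = _as_labels(pred_labels, true_labels)
    if labels is None:
        labels = sorted(set(trues) | set(preds))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for p, t in zip(preds, trues):
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, counts / row_sums, 0.0)
    return pd.DataFrame(norm, index=labels, columns=labels)
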