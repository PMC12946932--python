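"""Confusion-matrix construction and classification metrics for checklist evaluation.

Every (post, item) decision contributes one confusion-matrix cell; accuracy,
precision, recall and F1 follow the standard formulas with explicit
zero-division conventions (0, never NaN).  The default report is micro-averaged
(all 9xN decisions pooled into one matrix); macro and per-item views are also
provided since pooled single-number tables do not say which convention they
used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .classifier import Checklist
from .errors import ValidationError
from .ontology import ITEMS


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mode: str = "micro"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mode": self.mode,
        }


def _answers_of(obj) -> Mapping[str, str]:
    if isinstance(obj, Checklist):
        return obj.answers
    return obj


def confusion(
    predicted: Sequence, gold: Sequence[Mapping[str, str]], items: Sequence[str] = ITEMS
) -> ConfusionMatrix:
    """Pool all (post, item) yes/no decisions into one confusion matrix."""
    if len(predicted) != len(gold):
        raise ValidationError(
            f"predicted ({len(predicted)}) and gold ({len(gold)}) lengths differ"
        )
    tp = tn = fp = fn = 0
    for pred_obj, gold_map in zip(predicted, gold):
        pred = _answers_of(pred_obj)
        missing = [k for k in items if k not in gold_map or k not in pred]
        if missing:
            raise ValidationError(f"missing item keys: {missing}")
        for k in items:
            p = str(pred[k]).lower() == "yes"
            g = str(gold_map[k]).lower() == "yes"
            if p and g:
                tp += 1
            elif not p and not g:
                tn += 1
            elif p and not g:
                fp += 1
            else:
                fn += 1
    return ConfusionMatrix(tp, tn, fp, fn)


def metrics(cm: ConfusionMatrix, mode: str = "micro") -> MetricsReport:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    Conventions: precision := 0 when TP+FP = 0, recall := 0 when TP+FN = 0,
    F1 := 0 when precision + recall = 0.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = (cm.TP + cm.TN) / cm.total
    precision = cm.TP / (cm.TP + cm.FP) if (cm.TP + cm.FP) > 0 else 0.0
    recall = cm.TP / (cm.TP + cm.FN) if (cm.TP + cm.FN) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MetricsReport(accuracy, precision, recall, f1, mode)


def evaluate_checklists(
    predicted: Sequence, gold: Sequence[Mapping[str, str]]
) -> dict:
    """Full evaluation report: micro, macro and per-item metrics + pooled cells."""
    pooled = confusion(predicted, gold)
    per_item_cms = {k: confusion(predicted, gold, items=[k]) for k in ITEMS}
    per_item = {k: metrics(cm, mode="per_item").to_dict() for k, cm in per_item_cms.items()}
    per_item_reports = [metrics(cm, mode="per_item") for cm in per_item_cms.values()]
    n = len(per_item_reports)
    macro = {
        "accuracy": sum(r.accuracy for r in per_item_reports) / n,
        "precision": sum(r.precision for r in per_item_reports) / n,
        "recall": sum(r.recall for r in per_item_reports) / n,
        "f1": sum(r.f1 for r in per_item_reports) / n,
        "mode": "macro",
    }
    return {
        "micro": metrics(pooled, mode="micro").to_dict(),
        "macro": macro,
        "per_item": per_item,
        "confusion": {"TP": pooled.TP, "TN": pooled.TN, "FP": pooled.FP, "FN": pooled.FN},
    }
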