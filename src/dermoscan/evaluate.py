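"""Binary-classification evaluation: confusion matrix and seven metrics.

Metrics (from exact integer counts, floating division last):

* accuracy    = (TP + TN) / (TP + TN + FP + FN)
* sensitivity = TP / (TP + FN)                    (recall, true-positive rate)
* specificity = TN / (FP + TN)                    (true-negative rate)
* precision   = TP / (TP + FP)                    (positive predictive value)
* F1 (Dice)   = 2 * precision * recall / (precision + recall)
* Jaccard     = F1 / (2 - F1)   (equivalently TP / (TP + FP + FN))
* MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Zero denominators surface as explicit ``None`` entries (named in
``MetricsReport.undefined``), never as silent zeros.

:func:`reconstruct_confusion_from_metrics` inverts printed percentage metrics
back to the smallest integer confusion matrix consistent with them, accepting
both round-half-up and truncation since published tables mix the two
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "jaccard_from_f1",
    "reconstruct_confusion_from_metrics",
    "matches_printed",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The seven metrics; entries are None when their denominator is zero."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    jaccard: float | None
    mcc: float | None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "jaccard": self.jaccard,
            "mcc": self.mcc,
            "undefined": list(self.undefined),
        }


def confusion_matrix(
    true_labels: Sequence, predicted_labels: Sequence, positive_class
) -> ConfusionMatrix:
    """Standard 2x2 cross-tabulation with the stated positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences have different lengths")
    classes = set(true_labels) | set(predicted_labels)
    if len(classes) > 2:
        raise ValueError(f"more than two classes present: {sorted(map(str, classes))}")
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == positive_class and p == positive_class:
            tp += 1
        elif t != positive_class and p == positive_class:
            fp += 1
        elif t == positive_class and p != positive_class:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All seven metrics from integer counts; zero denominators yield None."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    undefined: list[str] = []

    def frac(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    accuracy = frac(cm.tp + cm.tn, cm.total, "accuracy")
    sensitivity = frac(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = frac(cm.tn, cm.fp + cm.tn, "specificity")
    precision = frac(cm.tp, cm.tp + cm.fp, "precision")
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        if "precision" not in undefined and "sensitivity" not in undefined:
            undefined.append("f1")
        f1 = None
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    jaccard = None if f1 is None else f1 / (2.0 - f1)
    if f1 is None:
        undefined.append("jaccard")
    denom = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = None
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        jaccard=jaccard,
        mcc=mcc,
        undefined=tuple(dict.fromkeys(undefined)),
    )


def jaccard_from_f1(f1: float) -> float:
    """Jaccard (intersection over union) from the Dice/F1 score: F1/(2-F1)."""
    if not (0.0 <= f1 <= 1.0):
        raise ValueError(f"f1 must be in [0, 1], got {f1}")
    return f1 / (2.0 - f1)


def _printed_decimals(printed: float | str) -> tuple[float, int]:
    s = str(printed)
    decimals = len(s.split(".")[1]) if "." in s else 0
    return float(s), decimals


def matches_printed(computed: float, printed: float | str) -> bool:
    """True if ``computed`` rounds (half-up) OR truncates to the printed value
    at the printed number of decimals."""
    target, decimals = _printed_decimals(printed)
    scale = 10.0**decimals
    rounded = math.floor(computed * scale + 0.5) / scale
    truncated = math.floor(computed * scale + 1e-9) / scale
    return abs(rounded - target) < 1e-9 or abs(truncated - target) < 1e-9


def reconstruct_confusion_from_metrics(
    precision_pct: float | str,
    sensitivity_pct: float | str,
    specificity_pct: float | str,
    max_total: int = 200,
) -> ConfusionMatrix | None:
    """Smallest integer confusion matrix whose percentages print as given.

    Exhaustive search over TP+FP+FN+TN <= max_total, total ascending then TP
    ascending; a candidate matches when each computed percentage rounds OR
    truncates to the printed value at its printed precision.  Returns None if
    no consistent matrix exists within ``max_total``.
    """
    for v in (precision_pct, sensitivity_pct, specificity_pct):
        val = float(str(v))
        if not (0.0 <= val <= 100.0):
            raise ValueError(f"percentages must be in [0, 100], got {v}")
    if max_total < 2:
        raise ValueError("max_total must be >= 2")
    for total in range(2, max_total + 1):
        for tp in range(0, total + 1):
            for fn in range(0, total - tp + 1):
                if tp + fn > 0:
                    sens = 100.0 * tp / (tp + fn)
                    if not matches_printed(sens, sensitivity_pct):
                        continue
                elif float(str(sensitivity_pct)) != 0.0:
                    continue
                for fp in range(0, total - tp - fn + 1):
                    tn = total - tp - fn - fp
                    if tp + fp == 0 or tn + fp == 0:
                        continue
                    prec = 100.0 * tp / (tp + fp)
                    if not matches_printed(prec, precision_pct):
                        continue
                    spec = 100.0 * tn / (tn + fp)
                    if not matches_printed(spec, specificity_pct):
                        continue
                    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    return None
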