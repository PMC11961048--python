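"""Abstention-aware performance metrics for three-class diagnosis.

Confusion matrices here have three true-label rows (MEL, NV, BKL) and four
prediction columns (MEL, NV, BKL, NULL).  Abstention (NULL) is always
scored as an incorrect prediction — it counts in every recall denominator
but never in a precision denominator, and it is never treated as a fourth
class with its own precision.  Consequently the overall F1 reported here is
a *micro* F1 whose precision pools only non-NULL predictions while its
recall pools all samples; with no abstentions it degenerates to plain
accuracy.

Per-class "accuracy" means class-conditional accuracy, i.e. recall:
the fraction of samples of one true class predicted as that class.

A matrix may carry declared per-class supports that differ from its row
sums (some published matrices are internally inconsistent); recall-type
denominators then use the declared supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    AGE_GROUPS,
    DIAGNOSES,
    PREDICTED_LABELS,
    SEX_GROUPS,
    AgeGroup,
    Diagnosis,
    Predicted,
    PredictionRecord,
    Sex,
    ValidationError,
)

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "OverallMetrics",
    "EmptyStratumError",
    "confusion_matrix",
    "confusion_from_counts",
    "class_conditional_accuracy",
    "class_precision",
    "class_f1",
    "overall_metrics",
    "performance_table",
    "random_baseline",
]

_CLS_INDEX = {d: i for i, d in enumerate(DIAGNOSES)}
_PRED_INDEX = {p: i for i, p in enumerate(PREDICTED_LABELS)}


class EmptyStratumError(ValidationError):
    """No records fall in the requested stratum."""


@dataclass
class ConfusionMatrix:
    """3 true x 4 predicted (incl. NULL) counts for one stratum."""

    counts: np.ndarray
    stratum: str = "All"
    support: tuple[int, int, int] | None = None  # declared per-class supports

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 4):
            raise ValidationError(f"confusion matrix must be 3x4, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("negative confusion-matrix cell")
        if self.support is None:
            self.support = tuple(int(s) for s in self.counts.sum(axis=1))
        elif tuple(self.support) != tuple(self.counts.sum(axis=1)):
            warnings.warn(
                f"{self.stratum}: row sums {self.counts.sum(axis=1).tolist()} "
                f"differ from declared supports {list(self.support)}; "
                "recall denominators use the declared supports",
                stacklevel=2,
            )

    @property
    def total(self) -> int:
        return int(sum(self.support))

    @property
    def n_abstained(self) -> int:
        return int(self.counts[:, _PRED_INDEX[Predicted.NULL]].sum())

    def row(self, cls: Diagnosis) -> np.ndarray:
        return self.counts[_CLS_INDEX[cls]]

    def class_support(self, cls: Diagnosis) -> int:
        return int(self.support[_CLS_INDEX[cls]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[d.value for d in DIAGNOSES],
            columns=[p.value for p in PREDICTED_LABELS],
        )


@dataclass
class ClassMetrics:
    cls: Diagnosis
    recall: float
    precision: float  # NaN when no predictions of this class
    f1: float  # NaN when undefined (zero support and zero predictions)
    support: int


@dataclass
class OverallMetrics:
    accuracy: float
    micro_f1: float
    n_abstained: int
    n: int


_FACTOR_LEVELS: dict[str, tuple] = {
    "sex": SEX_GROUPS,
    "age_group": AGE_GROUPS,
}


def confusion_matrix(
    records: Sequence[PredictionRecord],
    factor: str | None = None,
    group: Sex | AgeGroup | None = None,
) -> ConfusionMatrix:
    """Count (true, predicted) pairs, optionally restricted to one stratum."""
    name = "All"
    if factor is not None:
        records = [r for r in records if r.group(factor) == group]
        name = f"{factor}={getattr(group, 'value', group)}"
    if not records:
        raise EmptyStratumError(f"no records in stratum {name}")
    counts = np.zeros((3, 4), dtype=np.int64)
    for r in records:
        if r.predicted_label is None:
            raise ValidationError(f"record {r.record_id} has no prediction")
        counts[_CLS_INDEX[r.true_label], _PRED_INDEX[r.predicted_label]] += 1
    return ConfusionMatrix(counts, stratum=name)


def confusion_from_counts(
    rows: Mapping[str, Sequence[int]],
    stratum: str = "All",
    support: Mapping[str, int] | None = None,
) -> ConfusionMatrix:
    """Build a matrix from a {true class: 4 prediction counts} mapping."""
    counts = np.array([rows[d.value] for d in DIAGNOSES], dtype=np.int64)
    sup = tuple(int(support[d.value]) for d in DIAGNOSES) if support else None
    return ConfusionMatrix(counts, stratum=stratum, support=sup)


def class_conditional_accuracy(cm: ConfusionMatrix, cls: Diagnosis) -> float:
    """Recall: diagonal count over class support; NULL counts as incorrect."""
    sup = cm.class_support(cls)
    if sup == 0:
        return float("nan")
    return float(cm.row(cls)[_CLS_INDEX[cls]]) / sup


def class_precision(cm: ConfusionMatrix, cls: Diagnosis) -> float:
    """Diagonal over all (non-NULL, by construction) predictions of cls."""
    col = cm.counts[:, _CLS_INDEX[cls]]
    predicted = int(col.sum())
    if predicted == 0:
        return float("nan")
    return float(col[_CLS_INDEX[cls]]) / predicted


def class_f1(cm: ConfusionMatrix, cls: Diagnosis) -> float:
    """Harmonic mean of per-class precision and recall.

    With zero predictions of the class the F1 is 0 when the class has
    support (nothing was retrieved), and NaN (undefined, printed N/A)
    when the class also has no support in the stratum.
    """
    recall = class_conditional_accuracy(cm, cls)
    precision = class_precision(cm, cls)
    if np.isnan(recall) and np.isnan(precision):
        return float("nan")
    if np.isnan(precision):  # support > 0, nothing predicted
        return 0.0
    if np.isnan(recall):
        return float("nan")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def class_metrics(cm: ConfusionMatrix, cls: Diagnosis) -> ClassMetrics:
    return ClassMetrics(
        cls=cls,
        recall=class_conditional_accuracy(cm, cls),
        precision=class_precision(cm, cls),
        f1=class_f1(cm, cls),
        support=cm.class_support(cls),
    )


def overall_metrics(cm: ConfusionMatrix) -> OverallMetrics:
    """Overall accuracy and abstention-aware micro F1.

    accuracy   = trace / n
    micro_f1   = harmonic mean of micro-precision (trace over non-NULL
                 predictions) and micro-recall (trace over n)
    """
    total = cm.total
    if total == 0:
        raise ValidationError("empty confusion matrix")
    trace = int(np.trace(cm.counts[:, :3]))
    non_null = int(cm.counts[:, :3].sum())
    accuracy = trace / total
    micro_recall = accuracy
    if non_null == 0:
        micro_f1 = 0.0
    else:
        micro_precision = trace / non_null
        denom = micro_precision + micro_recall
        micro_f1 = 0.0 if denom == 0 else 2 * micro_precision * micro_recall / denom
    return OverallMetrics(
        accuracy=accuracy, micro_f1=micro_f1, n_abstained=cm.n_abstained, n=total
    )


def performance_table(
    records: Sequence[PredictionRecord],
    factors: Sequence[str] = ("sex", "age_group"),
) -> pd.DataFrame:
    """Per-factor, per-group and overall performance decomposition.

    One row per (factor, group) plus a pooled "All" row; columns are the
    class-conditional accuracies and F1 scores for each diagnosis and the
    overall accuracy / micro-F1.  Strata with no records are omitted;
    UNKNOWN demographic levels are never stratified on.
    """
    rows = []

    def _emit(factor: str, group_name: str, cm: ConfusionMatrix) -> None:
        om = overall_metrics(cm)
        row: dict[str, object] = {"factor": factor, "group": group_name}
        for d in DIAGNOSES:
            row[f"acc_{d.value}"] = class_conditional_accuracy(cm, d)
            row[f"f1_{d.value}"] = class_f1(cm, d)
        row["acc_All"] = om.accuracy
        row["f1_All"] = om.micro_f1
        row["n"] = om.n
        row["n_abstained"] = om.n_abstained
        rows.append(row)

    for factor in factors:
        for level in _FACTOR_LEVELS[factor]:
            try:
                cm = confusion_matrix(records, factor, level)
            except EmptyStratumError:
                continue
            _emit(factor, level.value, cm)
    _emit("all", "All", confusion_matrix(records))
    return pd.DataFrame(rows)


def random_baseline(
    records: Sequence[PredictionRecord], seed: int
) -> list[Predicted]:
    """Uniform random diagnosis per record (never abstains); seeded."""
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 3, size=len(records))
    labels = [Predicted(DIAGNOSES[i].value) for i in draws]
    return labels
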