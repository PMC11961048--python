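"""Data model and delimited-text I/O for classifier prediction records.

A *prediction record* is one evaluated test case: the true diagnosis, the
predicted diagnosis (which may be an abstention), and the sensitive
attributes (sex, age group) used in the fairness audit.  The three diagnoses
are melanoma (MEL), melanocytic nevi (NV) and benign keratosis-like lesions
(BKL); the prediction space adds NULL for responses from which no diagnosis
could be extracted.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Diagnosis",
    "Predicted",
    "Sex",
    "AgeGroup",
    "PredictionRecord",
    "CohortTable",
    "ValidationError",
    "ConfigurationError",
    "DIAGNOSES",
    "PREDICTED_LABELS",
    "bin_age",
    "read_records",
    "write_records",
    "tabulate_cohort",
    "write_table",
]


class ValidationError(ValueError):
    """Raised when input data violates a documented invariant."""


class ConfigurationError(ValueError):
    """Raised when a file or configuration is structurally unusable."""


class Diagnosis(str, Enum):
    """True-label space, in canonical order MEL < NV < BKL."""

    MEL = "MEL"
    NV = "NV"
    BKL = "BKL"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.value


class Predicted(str, Enum):
    """Predicted-label space: the three diagnoses plus NULL (abstention)."""

    MEL = "MEL"
    NV = "NV"
    BKL = "BKL"
    NULL = "NULL"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Sex(str, Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"
    UNKNOWN = "UNKNOWN"


class AgeGroup(str, Enum):
    YOUNG = "YOUNG"
    MIDDLE = "MIDDLE"
    SENIOR = "SENIOR"
    UNKNOWN = "UNKNOWN"


#: Canonical orderings used by every table and report.
DIAGNOSES: tuple[Diagnosis, ...] = (Diagnosis.MEL, Diagnosis.NV, Diagnosis.BKL)
PREDICTED_LABELS: tuple[Predicted, ...] = (
    Predicted.MEL,
    Predicted.NV,
    Predicted.BKL,
    Predicted.NULL,
)
SEX_GROUPS: tuple[Sex, ...] = (Sex.FEMALE, Sex.MALE)
AGE_GROUPS: tuple[AgeGroup, ...] = (AgeGroup.YOUNG, AgeGroup.MIDDLE, AgeGroup.SENIOR)

# Synonym tables for case-insensitive label normalization.  Unrecognized
# strings are *errors*, never silently NULL: abstention is a semantic
# outcome, not a parse failure.
_DIAGNOSIS_SYNONYMS: dict[str, Diagnosis] = {}
for _canon, _names in {
    Diagnosis.MEL: ["mel", "mel.", "melanoma"],
    Diagnosis.NV: [
        "nv",
        "mn",
        "nevus",
        "nevi",
        "naevus",
        "melanocytic nevi",
        "melanocytic nevus",
        "melanocytic naevi",
    ],
    Diagnosis.BKL: [
        "bkl",
        "benign keratosis",
        "benign keratosis-like lesion",
        "benign keratosis-like lesions",
        "seborrheic keratosis",
    ],
}.items():
    for _n in _names:
        _DIAGNOSIS_SYNONYMS[_n] = _canon

_PREDICTED_SYNONYMS: dict[str, Predicted] = {
    k: Predicted(v.value) for k, v in _DIAGNOSIS_SYNONYMS.items()
}
for _n in ["null", "none", "abstain", "abstained", "uninterpretable", "n/a", "na"]:
    _PREDICTED_SYNONYMS[_n] = Predicted.NULL

_SEX_SYNONYMS = {
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
    "unknown": Sex.UNKNOWN,
    "u": Sex.UNKNOWN,
    "": Sex.UNKNOWN,
}

_AGE_GROUP_SYNONYMS = {
    "young": AgeGroup.YOUNG,
    "middle": AgeGroup.MIDDLE,
    "middle-aged": AgeGroup.MIDDLE,
    "middle aged": AgeGroup.MIDDLE,
    "senior": AgeGroup.SENIOR,
    "unknown": AgeGroup.UNKNOWN,
    "": AgeGroup.UNKNOWN,
}


def _normalize(value: str, table: Mapping[str, object], what: str, line: int | None = None):
    key = value.strip().lower()
    if key in table:
        return table[key]
    where = f" (line {line})" if line is not None else ""
    raise ValidationError(f"unmappable {what} label {value!r}{where}")


def parse_diagnosis(value: str, line: int | None = None) -> Diagnosis:
    return _normalize(value, _DIAGNOSIS_SYNONYMS, "diagnosis", line)


def parse_predicted(value: str, line: int | None = None) -> Predicted:
    return _normalize(value, _PREDICTED_SYNONYMS, "prediction", line)


def bin_age(age_years: float) -> AgeGroup:
    """Map an age in years to its audit age group.

    Bins: Young = 0-39, Middle-aged = 40-59, Senior = 60 and over.
    Fractional ages floor to integer years before binning.
    """
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return AgeGroup.UNKNOWN
    if age_years < 0:
        raise ValidationError(f"negative age: {age_years}")
    years = int(math.floor(age_years))
    if years <= 39:
        return AgeGroup.YOUNG
    if years <= 59:
        return AgeGroup.MIDDLE
    return AgeGroup.SENIOR


@dataclass
class PredictionRecord:
    """One evaluated test case (Y, Y-hat, sensitive attributes)."""

    record_id: str
    true_label: Diagnosis
    predicted_label: Predicted | None = None
    sex: Sex = Sex.UNKNOWN
    age_years: int | None = None
    age_group: AgeGroup = AgeGroup.UNKNOWN
    response_text: str | None = None

    def __post_init__(self) -> None:
        if self.age_years is not None:
            if self.age_years < 0:
                raise ValidationError(
                    f"record {self.record_id}: negative age {self.age_years}"
                )
            derived = bin_age(self.age_years)
            if self.age_group is AgeGroup.UNKNOWN:
                self.age_group = derived
            elif self.age_group is not derived:
                raise ValidationError(
                    f"record {self.record_id}: age_group {self.age_group.value} "
                    f"inconsistent with age {self.age_years} ({derived.value})"
                )

    def group(self, factor: str):
        """The record's level for a stratification factor ('sex'/'age_group')."""
        if factor == "sex":
            return self.sex
        if factor == "age_group":
            return self.age_group
        raise ConfigurationError(f"unknown factor {factor!r}")


_REQUIRED_COLUMNS = ("record_id", "true_label", "predicted_label")
_KNOWN_COLUMNS = _REQUIRED_COLUMNS + ("sex", "age_years", "age_group", "response_text")


def read_records(path: str | Path, delimiter: str = "\t") -> list[PredictionRecord]:
    """Read prediction records from a delimited text file.

    The header must name ``record_id``, ``true_label`` and
    ``predicted_label``, and at least one of the sensitive-attribute
    columns (``sex``, ``age_years``, ``age_group``).  Labels are
    normalized case-insensitively through the documented synonym tables;
    every malformed row is rejected with a line-numbered diagnostic.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ConfigurationError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        if not any(c in header for c in ("sex", "age_years", "age_group")):
            raise ConfigurationError(
                f"{path}: need at least one of sex/age_years/age_group"
            )
        records: list[PredictionRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            rid = (row.get("record_id") or "").strip()
            if not rid:
                raise ValidationError(f"{path}: empty record_id (line {lineno})")
            if rid in seen:
                raise ValidationError(f"{path}: duplicate record_id {rid!r} (line {lineno})")
            seen.add(rid)
            pred_raw = (row.get("predicted_label") or "").strip()
            age_raw = (row.get("age_years") or "").strip()
            age = int(float(age_raw)) if age_raw else None
            group_raw = (row.get("age_group") or "").strip()
            records.append(
                PredictionRecord(
                    record_id=rid,
                    true_label=parse_diagnosis(row["true_label"], lineno),
                    predicted_label=parse_predicted(pred_raw, lineno) if pred_raw else None,
                    sex=_normalize(row.get("sex") or "", _SEX_SYNONYMS, "sex", lineno),
                    age_years=age,
                    age_group=_normalize(
                        group_raw, _AGE_GROUP_SYNONYMS, "age group", lineno
                    ),
                    response_text=(row.get("response_text") or None),
                )
            )
    return records


def write_records(
    records: Sequence[PredictionRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write records as delimited text; round-trip stable with read_records."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_KNOWN_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.true_label.value,
                    r.predicted_label.value if r.predicted_label else "",
                    r.sex.value,
                    r.age_years if r.age_years is not None else "",
                    r.age_group.value,
                    r.response_text or "",
                ]
            )


@dataclass
class CohortTable:
    """Group x diagnosis counts with margins (a cohort composition table)."""

    factor: str
    counts: pd.DataFrame  # rows: group levels, cols: diagnoses; ints

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    @property
    def ratios(self) -> pd.Series:
        return self.row_totals / self.total

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["All"] = self.row_totals
        out.loc["All"] = out.sum(axis=0)
        return out

    def to_json(self) -> str:
        payload = {
            "factor": self.factor,
            "counts": {g: {d: int(v) for d, v in row.items()} for g, row in self.counts.iterrows()},
            "row_totals": {g: int(v) for g, v in self.row_totals.items()},
            "col_totals": {d: int(v) for d, v in self.col_totals.items()},
            "total": self.total,
        }
        return json.dumps(payload, indent=2)


def tabulate_cohort(
    records: Sequence[PredictionRecord], factor: str = "sex"
) -> CohortTable:
    """Cross-tabulate the cohort by a demographic factor and diagnosis.

    Every known factor level is retained even when empty; UNKNOWN rows are
    kept in the table (they are excluded only from stratified fairness
    statistics, not from cohort accounting).
    """
    if not records:
        raise ValidationError("cannot tabulate an empty cohort")
    levels: Sequence = SEX_GROUPS + (Sex.UNKNOWN,) if factor == "sex" else AGE_GROUPS + (AgeGroup.UNKNOWN,)
    counts = pd.DataFrame(
        0, index=[g.value for g in levels], columns=[d.value for d in DIAGNOSES], dtype=int
    )
    for r in records:
        counts.loc[r.group(factor).value, r.true_label.value] += 1
    return CohortTable(factor=factor, counts=counts)


def write_table(table: CohortTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "json":
        path.write_text(table.to_json() + "\n", encoding="utf-8")
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        buf = io.StringIO()
        table.to_frame().to_csv(buf, sep=sep)
        path.write_text(buf.getvalue(), encoding="utf-8")
    else:
        raise ConfigurationError(f"unknown table format {format!r}")
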