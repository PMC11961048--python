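"""Seeded synthetic cohorts and classifier simulators.

The generator emulates the *metadata level* of a dermatoscopic
evaluation study: a test cohort whose sex x disease and age x disease
margins match the published composition exactly (972 records; 335
melanoma / 305 melanocytic nevi / 332 benign keratosis-like lesions; 411
female / 561 male; 112 young / 375 middle-aged / 484 senior), and
classifiers whose behavior is a per-true-class probability distribution
over the four prediction outcomes, obtained by row-normalizing a
published confusion matrix.  Optionally a profile carries per-group
vectors so that a controlled true-positive-rate gap can be injected for
power studies.

Only the two margins are published, so the joint sex x age layout within
each disease is randomized (a seeded pairing of the two margin streams);
none of the implemented statistics stratify on sex and age jointly.
Ages are drawn uniformly within the record's age bin.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fixtures import CLASS_SUPPORTS, CONFUSION_MATRICES, TEST_COHORT_AGE, TEST_COHORT_SEX
from .metrics import ConfusionMatrix, confusion_from_counts
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
    "CohortSpec",
    "ClassifierProfile",
    "ham10000_test_cohort",
    "generate_cohort",
    "profile_from_confusion",
    "load_fixture_profile",
    "simulate_predictions",
    "inject_bias",
]

#: Uniform age ranges per bin (inclusive); the senior cap matches the
#: oldest ages seen in dermatoscopic registries.
_AGE_RANGES = {AgeGroup.YOUNG: (0, 39), AgeGroup.MIDDLE: (40, 59), AgeGroup.SENIOR: (60, 85)}


def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` proportional to `values`."""
    if values.sum() == 0:
        raise ValidationError("cannot apportion over all-zero counts")
    quotas = values / values.sum() * total
    floors = np.floor(quotas).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(quotas - floors))
    floors[order[:short]] += 1
    return floors


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition as two margins: sex x disease and age x disease.

    Per-disease totals must agree between the two margins.  The default
    (:func:`ham10000_test_cohort`) replicates the published test cohort.
    """

    sex_counts: Mapping[str, Mapping[str, int]]  # disease -> sex -> count
    age_counts: Mapping[str, Mapping[str, int]]  # disease -> age group -> count
    # age_counts may carry an "UNKNOWN" slot for records with missing age
    # (the published test cohort has one such BKL record: its age-group
    # margins sum to 331 against a BKL support of 332).

    def __post_init__(self) -> None:
        for d in DIAGNOSES:
            s = sum(self.sex_counts[d.value].values())
            a = sum(self.age_counts[d.value].values())
            if s != a:
                raise ValidationError(
                    f"{d.value}: sex margin total {s} != age margin total {a}"
                )
            if any(v < 0 for v in self.sex_counts[d.value].values()) or any(
                v < 0 for v in self.age_counts[d.value].values()
            ):
                raise ValidationError(f"{d.value}: negative cohort count")

    @property
    def total(self) -> int:
        return sum(sum(v.values()) for v in self.sex_counts.values())

    def disease_total(self, d: Diagnosis) -> int:
        return sum(self.sex_counts[d.value].values())

    def scaled(self, n: int) -> "CohortSpec":
        """A spec with the same composition apportioned to `n` records."""
        disease_totals = np.array([self.disease_total(d) for d in DIAGNOSES])
        targets = _largest_remainder(disease_totals, n)
        sex_c, age_c = {}, {}
        for d, target in zip(DIAGNOSES, targets):
            sex_keys = list(self.sex_counts[d.value])
            age_keys = list(self.age_counts[d.value])
            sv = _largest_remainder(
                np.array([self.sex_counts[d.value][k] for k in sex_keys]), int(target)
            )
            av = _largest_remainder(
                np.array([self.age_counts[d.value][k] for k in age_keys]), int(target)
            )
            sex_c[d.value] = dict(zip(sex_keys, sv.tolist()))
            age_c[d.value] = dict(zip(age_keys, av.tolist()))
        return CohortSpec(sex_c, age_c)

    def to_json(self) -> str:
        return json.dumps(
            {"sex_counts": {k: dict(v) for k, v in self.sex_counts.items()},
             "age_counts": {k: dict(v) for k, v in self.age_counts.items()}},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        data = json.loads(text)
        return cls(data["sex_counts"], data["age_counts"])


def ham10000_test_cohort() -> CohortSpec:
    """The published 972-record test-cohort composition."""
    sex_c = {d.value: {} for d in DIAGNOSES}
    age_c = {d.value: {} for d in DIAGNOSES}
    for g, row in TEST_COHORT_SEX.items():
        for d, v in row.items():
            sex_c[d][g] = v
    for g, row in TEST_COHORT_AGE.items():
        for d, v in row.items():
            age_c[d][g] = v
    # The published age margins cover 971 of the 972 test records; the
    # remaining BKL record has no recorded age.
    age_c["BKL"]["UNKNOWN"] = 1
    return CohortSpec(sex_c, age_c)


def generate_cohort(spec: CohortSpec, seed: int) -> list[PredictionRecord]:
    """Materialize a cohort with the spec's margins exactly.

    Within each disease the sex stream and the age stream are paired by a
    seeded shuffle, so both margins are exact while the joint layout is
    randomized.  Predictions are left empty.
    """
    rng = np.random.default_rng(seed)
    records: list[PredictionRecord] = []
    idx = 0
    for d in DIAGNOSES:
        sexes: list[Sex] = []
        for g in (*SEX_GROUPS, Sex.UNKNOWN):
            sexes += [g] * spec.sex_counts[d.value].get(g.value, 0)
        ages: list[AgeGroup] = []
        for g in (*AGE_GROUPS, AgeGroup.UNKNOWN):
            ages += [g] * spec.age_counts[d.value].get(g.value, 0)
        rng.shuffle(ages)  # type: ignore[arg-type]
        for sex, age_group in zip(sexes, ages):
            if age_group is AgeGroup.UNKNOWN:
                age_years = None
            else:
                lo, hi = _AGE_RANGES[age_group]
                age_years = int(rng.integers(lo, hi + 1))
            records.append(
                PredictionRecord(
                    record_id=f"synth-{idx:05d}",
                    true_label=d,
                    sex=sex,
                    age_years=age_years,
                    age_group=age_group,
                )
            )
            idx += 1
    return records


@dataclass
class ClassifierProfile:
    """Per-true-class prediction distributions driving the simulator.

    ``vectors`` maps (disease, group) to a probability vector over the
    four outcomes (MEL, NV, BKL, NULL); the group key is None for
    group-independent behavior.  ``factor`` names the demographic factor
    the group keys refer to, or None.
    """

    vectors: dict[tuple[str, str | None], np.ndarray]
    factor: str | None = None

    def __post_init__(self) -> None:
        for key, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (4,) or (v < 0).any() or abs(v.sum() - 1) > 1e-9:
                raise ValidationError(f"invalid probability vector for {key}: {v}")
            self.vectors[key] = v

    def vector_for(self, disease: Diagnosis, group: str | None) -> np.ndarray:
        key = (disease.value, group if self.factor else None)
        if key in self.vectors:
            return self.vectors[key]
        base = (disease.value, None)
        if base in self.vectors:
            return self.vectors[base]
        raise ValidationError(f"profile has no vector for {key}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "factor": self.factor,
                "vectors": {
                    f"{d}|{g if g is not None else '*'}": v.tolist()
                    for (d, g), v in self.vectors.items()
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierProfile":
        data = json.loads(text)
        vectors = {}
        for key, v in data["vectors"].items():
            d, g = key.split("|")
            vectors[(d, None if g == "*" else g)] = np.array(v)
        return cls(vectors, data.get("factor"))


def profile_from_confusion(cm: ConfusionMatrix) -> ClassifierProfile:
    """Row-normalized confusion frequencies as a group-independent profile."""
    vectors = {}
    for i, d in enumerate(DIAGNOSES):
        row = cm.counts[i].astype(float)
        if row.sum() == 0:
            raise ValidationError(f"zero confusion row for {d.value}")
        vectors[(d.value, None)] = row / row.sum()
    return ClassifierProfile(vectors)


def load_fixture_profile(name: str) -> ClassifierProfile:
    """Profile for one of the packaged published confusion matrices."""
    if name not in CONFUSION_MATRICES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(CONFUSION_MATRICES))}"
        )
    cm = confusion_from_counts(CONFUSION_MATRICES[name], stratum=name)
    return profile_from_confusion(cm)


def simulate_predictions(
    cohort: Sequence[PredictionRecord], profile: ClassifierProfile, seed: int
) -> list[PredictionRecord]:
    """Fill predictions by independent draws from the applicable vector."""
    rng = np.random.default_rng(seed)
    out = []
    for r in cohort:
        group = r.group(profile.factor).value if profile.factor else None
        p = profile.vector_for(r.true_label, group)
        draw = rng.choice(4, p=p)
        out.append(dataclasses.replace(r, predicted_label=PREDICTED_LABELS[draw]))
    return out


def inject_bias(
    profile: ClassifierProfile,
    factor: str,
    group: str,
    cls: Diagnosis,
    delta: float,
) -> ClassifierProfile:
    """Raise one group's TPR for one class by `delta`.

    The target group's P(Yhat = cls | Y = cls) is increased by delta and
    the other three entries of that row are rescaled proportionally, so
    the error structure of the profile is preserved.  Every other group
    keeps the base behavior.  Only group-independent base profiles can be
    biased (one injection at a time).
    """
    if profile.factor is not None:
        raise ValidationError("can only inject bias into a group-independent profile")
    levels = SEX_GROUPS if factor == "sex" else AGE_GROUPS
    if group not in {g.value for g in levels}:
        raise ValidationError(f"unknown group {group!r} for factor {factor!r}")
    cls_idx = list(DIAGNOSES).index(cls)
    vectors: dict[tuple[str, str | None], np.ndarray] = {}
    for d in DIAGNOSES:
        base = profile.vector_for(d, None)
        for level in levels:
            v = base.copy()
            if d == cls and level.value == group:
                target = v[cls_idx] + delta
                if not (0.0 <= target <= 1.0):
                    raise ValidationError(
                        f"delta {delta} pushes P(correct|{cls.value}) to {target:.3f}, "
                        "outside [0, 1]"
                    )
                rest = 1.0 - v[cls_idx]
                if rest > 0:
                    v[np.arange(4) != cls_idx] *= (1.0 - target) / rest
                elif delta != 0:
                    raise ValidationError("row has no off-target mass to rescale")
                v[cls_idx] = target
                v /= v.sum()  # guard rounding drift
            vectors[(d.value, level.value)] = v
    return ClassifierProfile(vectors, factor=factor)
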