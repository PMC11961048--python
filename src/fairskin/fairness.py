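"""Group-fairness battery for multi-class diagnosis with abstention.

Two complementary instruments:

* a Pearson chi-square test of independence between demographic group and
  prediction correctness, on a G x 2 (correct, incorrect) contingency
  table, without continuity correction;

* rate-gap metrics built from one-vs-rest group rates.  For a target
  class, TPR_i = P(Yhat = c | Y = c, group i) and
  FPR_i = P(Yhat = c | Y != c, group i); abstention never counts as a
  positive prediction.  For n groups,

      avgTPRdiff = (2 / n(n-1)) * sum_{i<j} |TPR_i - TPR_j|
      avgFPRdiff = (2 / n(n-1)) * sum_{i<j} |FPR_i - FPR_j|
      AOD        = (avgTPRdiff + avgFPRdiff) / 2

  AOD is 0 iff all group rates are equal (the equalized-odds ideal).
  Companion metrics use min-ratio / max-gap multi-group conventions:
  disparate impact DI = min over pairs of the positive-prediction-rate
  ratio (<= 1, 1 = parity); equal-opportunity gap EOP = max pairwise
  |TPR_i - TPR_j|; equalized-odds gap EOD = max of the TPR and FPR
  pairwise gaps.

A model is adjudicated *biased* for a factor iff any scope's chi-square
p-value (per-disease or pooled) falls below the significance level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    AGE_GROUPS,
    DIAGNOSES,
    SEX_GROUPS,
    AgeGroup,
    Diagnosis,
    Predicted,
    PredictionRecord,
    Sex,
    ValidationError,
)

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "GroupRates",
    "FairnessSummary",
    "build_contingency",
    "contingency_from_counts",
    "chi_square_test",
    "group_rates",
    "average_tpr_difference",
    "average_fpr_difference",
    "aod",
    "disparate_impact",
    "equal_opportunity_gap",
    "equalized_odds_gap",
    "adjudicate_bias",
    "fairness_table",
]

#: Classical small-expected-count warning threshold.
MIN_EXPECTED_WARN = 5.0

_FACTOR_LEVELS: dict[str, tuple] = {"sex": SEX_GROUPS, "age_group": AGE_GROUPS}
_UNKNOWNS = (Sex.UNKNOWN, AgeGroup.UNKNOWN)


@dataclass
class ContingencyTable:
    """Group x {correct, incorrect} observed counts with expected frequencies."""

    groups: list[str]
    observed: np.ndarray  # shape (G, 2), ints

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=np.int64)
        if self.observed.ndim != 2 or self.observed.shape[1] != 2:
            raise ValidationError("contingency table must be G x 2")
        if len(self.groups) != self.observed.shape[0]:
            raise ValidationError("group labels do not match table rows")
        if (self.observed < 0).any():
            raise ValidationError("negative observed count")
        if len(self.groups) < 2:
            raise ValidationError("need at least 2 groups with samples")

    @property
    def expected(self) -> np.ndarray:
        """Expected cell counts from row/column margins (independence)."""
        row = self.observed.sum(axis=1, keepdims=True)
        col = self.observed.sum(axis=0, keepdims=True)
        return row * col / self.observed.sum()

    @property
    def df(self) -> int:
        return (self.observed.shape[0] - 1) * (self.observed.shape[1] - 1)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    min_expected: float

    @property
    def small_expected_warning(self) -> bool:
        return self.min_expected < MIN_EXPECTED_WARN


def contingency_from_counts(
    counts: Mapping[str, tuple[int, int]]
) -> ContingencyTable:
    """Table from a {group: (correct, incorrect)} mapping.

    Groups with zero totals are dropped with a warning; fewer than two
    surviving groups is an error.
    """
    groups, rows = [], []
    for g, (c, i) in counts.items():
        if c + i == 0:
            warnings.warn(f"group {g} has no samples; dropped from contingency table")
            continue
        groups.append(g)
        rows.append((c, i))
    return ContingencyTable(groups, np.array(rows))


def build_contingency(
    records: Sequence[PredictionRecord],
    factor: str,
    class_scope: Diagnosis | str = "all",
) -> ContingencyTable:
    """Group x correctness table for one factor.

    Correctness is (Yhat == Y); NULL is always incorrect.  ``class_scope``
    restricts the samples to one true class ("all" pools the three).
    UNKNOWN demographic levels are excluded.
    """
    counts: dict[str, list[int]] = {}
    for level in _FACTOR_LEVELS[factor]:
        counts[level.value] = [0, 0]
    for r in records:
        g = r.group(factor)
        if g in _UNKNOWNS:
            continue
        if class_scope != "all" and r.true_label != class_scope:
            continue
        correct = r.predicted_label is not None and r.predicted_label.value == r.true_label.value
        counts[g.value][0 if correct else 1] += 1
    return contingency_from_counts({g: tuple(v) for g, v in counts.items()})


def chi_square_test(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square of independence, no continuity correction.

    statistic = sum over cells of (O - E)^2 / E; p is the upper tail of
    the chi-square distribution with (G-1) degrees of freedom.  Expected
    cells below the classical threshold of 5 set a warning flag but the
    test is still computed.
    """
    expected = table.expected
    if (expected == 0).any():
        i, j = np.argwhere(expected == 0)[0]
        raise ValidationError(
            f"zero expected count in cell ({table.groups[i]}, "
            f"{'correct' if j == 0 else 'incorrect'})"
        )
    stat = float(((table.observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, table.df))
    return ChiSquareResult(
        statistic=stat, df=table.df, p_value=p, min_expected=float(expected.min())
    )


@dataclass
class GroupRates:
    """One-vs-rest TPR/FPR per demographic group for a target class."""

    cls: Diagnosis
    groups: list[str]
    tpr: np.ndarray  # NaN where a group has no positives
    fpr: np.ndarray  # NaN where a group has no negatives
    positive_rate: np.ndarray  # P(Yhat = cls) per group, for DI

    @property
    def n(self) -> int:
        return len(self.groups)


def group_rates(
    records: Sequence[PredictionRecord], factor: str, cls: Diagnosis
) -> GroupRates:
    """Per-group one-vs-rest rates for one target class."""
    levels = [g for g in _FACTOR_LEVELS[factor]]
    tpr, fpr, pos_rate, groups = [], [], [], []
    for level in levels:
        members = [r for r in records if r.group(factor) == level]
        if not members:
            continue
        groups.append(level.value)
        positives = [r for r in members if r.true_label == cls]
        negatives = [r for r in members if r.true_label != cls]
        predicted_pos = lambda r: (
            r.predicted_label is not None and r.predicted_label.value == cls.value
        )
        tpr.append(
            np.nan if not positives else sum(map(predicted_pos, positives)) / len(positives)
        )
        fpr.append(
            np.nan if not negatives else sum(map(predicted_pos, negatives)) / len(negatives)
        )
        pos_rate.append(sum(map(predicted_pos, members)) / len(members))
    if len(groups) < 2:
        raise ValidationError(f"factor {factor!r} has fewer than 2 populated groups")
    return GroupRates(cls, groups, np.array(tpr), np.array(fpr), np.array(pos_rate))


def _mean_abs_pairwise(values: np.ndarray) -> float:
    if np.isnan(values).any():
        return float("nan")
    pairs = list(itertools.combinations(range(len(values)), 2))
    if not pairs:
        raise ValidationError("need at least 2 groups")
    return float(np.mean([abs(values[i] - values[j]) for i, j in pairs]))


def average_tpr_difference(rates: GroupRates) -> float:
    """Mean absolute pairwise TPR difference over the n(n-1)/2 group pairs."""
    return _mean_abs_pairwise(rates.tpr)


def average_fpr_difference(rates: GroupRates) -> float:
    return _mean_abs_pairwise(rates.fpr)


def aod(rates: GroupRates) -> float:
    """Average odds difference: half the sum of the two pairwise averages."""
    return 0.5 * (average_tpr_difference(rates) + average_fpr_difference(rates))


def disparate_impact(rates: GroupRates) -> float:
    """Min over group pairs of the positive-prediction-rate ratio (<= 1)."""
    pr = rates.positive_rate
    if (pr == 0).any():
        return float("nan")
    ratios = [
        min(pr[i], pr[j]) / max(pr[i], pr[j])
        for i, j in itertools.combinations(range(len(pr)), 2)
    ]
    return float(min(ratios))


def equal_opportunity_gap(rates: GroupRates) -> float:
    """Max pairwise absolute TPR difference."""
    if np.isnan(rates.tpr).any():
        return float("nan")
    return float(np.max(rates.tpr) - np.min(rates.tpr))


def equalized_odds_gap(rates: GroupRates) -> float:
    """Max of the pairwise TPR and FPR gaps (both equalized-odds conditions)."""
    if np.isnan(rates.fpr).any():
        return float("nan")
    fpr_gap = float(np.max(rates.fpr) - np.min(rates.fpr))
    return max(equal_opportunity_gap(rates), fpr_gap)


def adjudicate_bias(
    p_values: Mapping[str, float], alpha: float = 0.05
) -> tuple[bool, list[str]]:
    """Verdict for one factor: biased iff any scope's p-value < alpha.

    Returns the verdict and the list of scopes (disease names or 'All')
    that contributed it.  NaN p-values never contribute.
    """
    contributing = [
        scope for scope, p in p_values.items() if not np.isnan(p) and p < alpha
    ]
    return bool(contributing), contributing


@dataclass
class FairnessSummary:
    """Per-factor fairness report: gaps, p-values and the bias verdict."""

    factor: str
    alpha: float
    per_class: pd.DataFrame  # rows per scope: aod, di, eop, eod, chi2, p
    biased: bool
    biased_scopes: list[str]


def fairness_table(
    records: Sequence[PredictionRecord],
    factors: Sequence[str] = ("sex", "age_group"),
    alpha: float = 0.05,
    pooled_aod: str = "mean",
) -> list[FairnessSummary]:
    """Run the full fairness battery for each factor.

    Scopes are the three diseases plus a pooled "All".  The pooled
    chi-square crosses group with correctness over all samples; the
    pooled AOD/EOP/EOD are unweighted means of the per-class one-vs-rest
    values (``pooled_aod='micro'`` instead averages the underlying group
    rates before taking gaps); the pooled DI uses the overall non-NULL
    positive-prediction rates.
    """
    if pooled_aod not in ("mean", "micro"):
        raise ValidationError(f"unknown pooled_aod mode {pooled_aod!r}")
    summaries = []
    for factor in factors:
        rows = []
        per_class_rates: list[GroupRates] = []
        for d in DIAGNOSES:
            rates = group_rates(records, factor, d)
            per_class_rates.append(rates)
            result = chi_square_test(build_contingency(records, factor, d))
            rows.append(
                {
                    "scope": d.value,
                    "aod": aod(rates),
                    "di": disparate_impact(rates),
                    "eop": equal_opportunity_gap(rates),
                    "eod": equalized_odds_gap(rates),
                    "chi2": result.statistic,
                    "p_value": result.p_value,
                    "min_expected": result.min_expected,
                }
            )
        pooled_chi = chi_square_test(build_contingency(records, factor, "all"))
        if pooled_aod == "mean":
            pooled_aod_v = float(np.mean([r["aod"] for r in rows]))
            pooled_eop = float(np.mean([r["eop"] for r in rows]))
            pooled_eod = float(np.mean([r["eod"] for r in rows]))
        else:  # micro: average group rates across classes, then take gaps
            tpr = np.mean([gr.tpr for gr in per_class_rates], axis=0)
            fpr = np.mean([gr.fpr for gr in per_class_rates], axis=0)
            micro = GroupRates(
                DIAGNOSES[0],
                per_class_rates[0].groups,
                tpr,
                fpr,
                np.mean([gr.positive_rate for gr in per_class_rates], axis=0),
            )
            pooled_aod_v = aod(micro)
            pooled_eop = equal_opportunity_gap(micro)
            pooled_eod = equalized_odds_gap(micro)
        pooled_di = float(np.nanmin([r["di"] for r in rows]))
        rows.append(
            {
                "scope": "All",
                "aod": pooled_aod_v,
                "di": pooled_di,
                "eop": pooled_eop,
                "eod": pooled_eod,
                "chi2": pooled_chi.statistic,
                "p_value": pooled_chi.p_value,
                "min_expected": pooled_chi.min_expected,
            }
        )
        frame = pd.DataFrame(rows).set_index("scope")
        verdict, scopes = adjudicate_bias(frame["p_value"].to_dict(), alpha)
        summaries.append(
            FairnessSummary(
                factor=factor,
                alpha=alpha,
                per_class=frame,
                biased=verdict,
                biased_scopes=scopes,
            )
        )
    return summaries
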