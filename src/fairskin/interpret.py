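"""Keyword-based interpretation of free-text diagnostic responses.

Multimodal chat models asked for a diagnosis tend to answer with a
paragraph rather than a label.  This module turns such free text into one
of the four prediction outcomes (MEL, NV, BKL or NULL) with a
deterministic, ordered keyword rule set, and provides dual-annotation
adjudication utilities for workflows where two humans label each response
independently and reconcile disagreements.

Precedence of :func:`interpret_response`:

1. a *final-answer*-scoped match nearest the end of the text,
2. a unique disease mentioned anywhere,
3. the most frequently mentioned disease, ties broken severity-first
   (MEL > NV > BKL),
4. NULL (uninterpretable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import Diagnosis, Predicted, ValidationError

__all__ = [
    "KeywordRule",
    "KeywordRuleSet",
    "AnnotationPair",
    "AgreementReport",
    "default_rules",
    "interpret_response",
    "adjudicate",
    "interpreter_accuracy",
]

#: Fraction of the text (from the end) treated as the "final answer" zone.
FINAL_ANSWER_FRACTION = 0.25

#: Markers whose last occurrence also opens the final-answer zone.
CONCLUSION_MARKERS = (
    ":",
    "conclusion",
    "in summary",
    "overall",
    "final answer",
    "most likely",
    "diagnosis is",
    "indicative of",
    "answer is",
)

#: Severity-first tie order (melanoma is the serious class).
TIE_ORDER: tuple[Predicted, ...] = (Predicted.MEL, Predicted.NV, Predicted.BKL)


@dataclass(frozen=True)
class KeywordRule:
    pattern: str
    target: Predicted
    scope: str = "anywhere"  # or "final-answer"

    def __post_init__(self) -> None:
        if self.target is Predicted.NULL:
            raise ValidationError("NULL is the fall-through outcome, never a rule target")
        if self.scope not in ("anywhere", "final-answer"):
            raise ValidationError(f"unknown rule scope {self.scope!r}")


@dataclass
class KeywordRuleSet:
    rules: list[KeywordRule]

    def __post_init__(self) -> None:
        targets = {r.target for r in self.rules}
        missing = {Predicted(d.value) for d in Diagnosis} - targets
        if missing:
            raise ValidationError(
                "rule set must cover every diagnosis; missing "
                + ", ".join(sorted(m.value for m in missing))
            )

    def __iter__(self):
        return iter(self.rules)


def default_rules() -> KeywordRuleSet:
    """Shipped rule set covering the three diagnoses and common synonyms."""
    mk = KeywordRule
    rules = []
    for scope in ("final-answer", "anywhere"):
        rules += [
            mk("melanoma", Predicted.MEL, scope),
            mk("melanocytic nevi", Predicted.NV, scope),
            mk("melanocytic nevus", Predicted.NV, scope),
            mk("nevus", Predicted.NV, scope),
            mk("nevi", Predicted.NV, scope),
            mk("benign keratosis", Predicted.BKL, scope),
            mk("keratosis-like", Predicted.BKL, scope),
            mk("seborrheic keratosis", Predicted.BKL, scope),
            mk("bkl", Predicted.BKL, scope),
        ]
    return KeywordRuleSet(rules)


def _match_spans(text_lower: str, pattern: str) -> list[tuple[int, int]]:
    """(start, end) spans of whole-word occurrences of a literal pattern."""
    return [
        m.span()
        for m in re.finditer(r"(?<!\w)" + re.escape(pattern.lower()) + r"(?!\w)", text_lower)
    ]


def _merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping spans so nested synonyms count as one mention."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(end, merged[-1][1]))
        else:
            merged.append((start, end))
    return merged


def _final_zone_start(text: str) -> int:
    """Offset where the final-answer zone begins.

    The zone is the last quarter of the text or the segment following the
    last conclusion marker, whichever starts later.
    """
    frac_start = int(len(text) * (1 - FINAL_ANSWER_FRACTION))
    marker_start = -1
    lower = text.lower()
    for marker in CONCLUSION_MARKERS:
        pos = lower.rfind(marker)
        if pos >= 0:
            marker_start = max(marker_start, pos + len(marker))
    return max(frac_start, marker_start)


def interpret_response(
    text: str | None, rules: KeywordRuleSet | None = None
) -> Predicted:
    """Interpret a free-text response into a prediction outcome.

    Pure function of (text, rules); never raises on arbitrary text —
    anything uninterpretable maps to NULL.
    """
    if not text or not text.strip():
        return Predicted.NULL
    rules = rules or default_rules()
    lower = text.lower()

    # Collect occurrences per rule once.
    hits: list[tuple[KeywordRule, list[tuple[int, int]]]] = []
    for rule in rules:
        spans = _match_spans(lower, rule.pattern)
        if spans:
            hits.append((rule, spans))
    if not hits:
        return Predicted.NULL

    # Tier 1: final-answer-scoped match nearest the end.
    zone = _final_zone_start(text)
    best_pos, best_target = -1, None
    for rule, spans in hits:
        if rule.scope != "final-answer":
            continue
        in_zone = [s for s, _ in spans if s >= zone]
        if in_zone and max(in_zone) > best_pos:
            best_pos, best_target = max(in_zone), rule.target
    if best_target is not None:
        return best_target

    # Tier 2/3: mentions anywhere.  Overlapping synonym matches (e.g.
    # "melanocytic nevi" also matching "nevi") merge into one mention.
    spans_by_target: dict[Predicted, set[tuple[int, int]]] = {}
    for rule, spans in hits:
        spans_by_target.setdefault(rule.target, set()).update(spans)
    counts = {t: len(_merge_spans(s)) for t, s in spans_by_target.items()}
    if len(counts) == 1:
        return next(iter(counts))
    max_count = max(counts.values())
    leaders = [t for t in TIE_ORDER if counts.get(t, 0) == max_count]
    return leaders[0]


@dataclass
class AnnotationPair:
    """Two independent labels for one response, with optional resolution."""

    record_id: str
    label_a: Predicted
    label_b: Predicted
    resolved: Predicted | None = None


@dataclass
class AgreementReport:
    n: int
    n_disagreements: int
    per_class_disagreements: dict[str, int]

    @property
    def agreement_rate(self) -> float:
        return 1.0 if self.n == 0 else 1.0 - self.n_disagreements / self.n


def adjudicate(
    pairs: Sequence[AnnotationPair],
) -> tuple[list[Predicted], AgreementReport]:
    """Resolve dual annotations into final labels.

    Agreeing pairs pass through; disagreeing pairs must carry an explicit
    resolution (the discuss-and-resolve step), otherwise a validation
    error lists the offending record ids.
    """
    unresolved = [p.record_id for p in pairs if p.label_a != p.label_b and p.resolved is None]
    if unresolved:
        raise ValidationError(
            "unresolved annotator disagreement for record(s): " + ", ".join(unresolved)
        )
    labels: list[Predicted] = []
    per_class: dict[str, int] = {}
    n_dis = 0
    for p in pairs:
        if p.label_a == p.label_b:
            labels.append(p.resolved if p.resolved is not None else p.label_a)
        else:
            n_dis += 1
            for lab in (p.label_a, p.label_b):
                per_class[lab.value] = per_class.get(lab.value, 0) + 1
            labels.append(p.resolved)
    return labels, AgreementReport(len(pairs), n_dis, per_class)


def interpreter_accuracy(
    predicted: Sequence[Predicted], truth: Sequence[Predicted]
) -> float:
    """Exact-match fraction over the four outcomes."""
    if len(predicted) != len(truth):
        raise ValidationError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if not predicted:
        raise ValidationError("empty label sequences")
    return sum(p == t for p, t in zip(predicted, truth)) / len(predicted)
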