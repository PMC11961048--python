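"""Report writers: JSON as the machine-of-record format, TSV for human diffing.

Every report echoes the configuration it was produced from, and labels
each metric with its definition identifier (e.g. ``micro-f1-with-abstention``)
so no number is ambiguous.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .fairness import FairnessSummary
from .metrics import ConfusionMatrix

__all__ = [
    "METRIC_DEFINITIONS",
    "write_json",
    "confusion_report",
    "performance_report",
    "fairness_report",
]

METRIC_DEFINITIONS = {
    "acc": "class-conditional-accuracy (recall; NULL scored incorrect)",
    "acc_All": "overall-accuracy (trace over n)",
    "f1": "per-class F1 (precision over non-NULL predictions)",
    "f1_All": "micro-f1-with-abstention",
    "aod": "average-odds-difference (mean |pairwise| TPR and FPR gaps, halved)",
    "di": "disparate-impact (min pairwise positive-rate ratio)",
    "eop": "equal-opportunity-gap (max pairwise TPR gap)",
    "eod": "equalized-odds-gap (max of TPR and FPR pairwise gaps)",
    "p_value": "Pearson chi-square upper-tail p, no continuity correction",
}


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if np.isnan(obj) else float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(payload: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonify(dict(payload)), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def confusion_report(cm: ConfusionMatrix) -> dict[str, Any]:
    return {
        "stratum": cm.stratum,
        "counts": {
            row: [int(v) for v in cm.counts[i]] for i, row in enumerate(("MEL", "NV", "BKL"))
        },
        "columns": ["MEL", "NV", "BKL", "NULL"],
        "support": list(cm.support),
    }


def performance_report(table: pd.DataFrame) -> dict[str, Any]:
    return {
        "definitions": METRIC_DEFINITIONS,
        "rows": _jsonify(table.to_dict(orient="records")),
    }


def fairness_report(summaries: Sequence[FairnessSummary]) -> dict[str, Any]:
    out: dict[str, Any] = {"definitions": METRIC_DEFINITIONS, "factors": {}}
    for s in summaries:
        out["factors"][s.factor] = {
            "alpha": s.alpha,
            "biased": s.biased,
            "biased_scopes": s.biased_scopes,
            "scopes": _jsonify(s.per_class.reset_index().to_dict(orient="records")),
        }
    return out
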