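"""Published evaluation artifacts of the HAM10000 three-disease audit.

These fixtures carry, as plain data, the study-level summaries of a
dermatoscopic skin-disease benchmark: the demographic composition of the
972-image test cohort (by sex and by age group, for melanoma / melanocytic
nevi / benign keratosis-like lesions) and the 3x4 confusion matrices
(MEL, NV, BKL rows; MEL, NV, BKL, NULL prediction columns) of seven
classifiers evaluated on that cohort, including two multimodal chat
models that may abstain.

Three of the printed matrices have a BKL row whose sum disagrees with the
BKL test support of 332 (they sum to 337, 328 and 331); they are carried
as printed, and consumers score them against the declared class supports.
"""

from __future__ import annotations

import math

__all__ = [
    "CLASS_SUPPORTS",
    "TEST_COHORT_SEX",
    "TEST_COHORT_AGE",
    "CONFUSION_MATRICES",
    "GROUP_ACCURACY",
    "round_half_up",
    "reconstructed_group_correct_counts",
]

#: Test-set support per true class (MEL, NV, BKL) — total 972.
CLASS_SUPPORTS: dict[str, int] = {"MEL": 335, "NV": 305, "BKL": 332}

#: Test-cohort counts, sex group x disease.
TEST_COHORT_SEX: dict[str, dict[str, int]] = {
    "FEMALE": {"MEL": 128, "NV": 145, "BKL": 138},
    "MALE": {"MEL": 207, "NV": 160, "BKL": 194},
}

#: Test-cohort counts, age group x disease.
TEST_COHORT_AGE: dict[str, dict[str, int]] = {
    "YOUNG": {"MEL": 24, "NV": 73, "BKL": 15},
    "MIDDLE": {"MEL": 119, "NV": 165, "BKL": 91},
    "SENIOR": {"MEL": 192, "NV": 67, "BKL": 225},
}

#: Confusion matrices: true class -> counts over (MEL, NV, BKL, NULL).
CONFUSION_MATRICES: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "chatgpt4-web": {
        "MEL": (251, 76, 3, 5),
        "NV": (141, 146, 15, 3),
        "BKL": (137, 112, 73, 10),
    },
    "llava-1.6": {
        "MEL": (127, 118, 11, 79),
        "NV": (60, 167, 8, 70),
        "BKL": (17, 37, 268, 6),  # printed row sums to 328, support is 332
    },
    "swin-b": {
        "MEL": (214, 69, 52, 0),
        "NV": (21, 271, 13, 0),
        "BKL": (36, 21, 275, 0),
    },
    "vgg16": {
        "MEL": (157, 101, 77, 0),
        "NV": (30, 268, 7, 0),
        "BKL": (199, 106, 32, 0),  # printed row sums to 337
    },
    "resnet50": {
        "MEL": (73, 60, 202, 0),
        "NV": (13, 241, 51, 0),
        "BKL": (167, 77, 88, 0),
    },
    "model-derm": {
        "MEL": (80, 30, 84, 141),
        "NV": (103, 45, 49, 108),
        "BKL": (37, 0, 207, 88),
    },
    "random": {
        "MEL": (93, 123, 119, 0),
        "NV": (84, 118, 103, 0),
        "BKL": (91, 126, 114, 0),  # printed row sums to 331
    },
}

#: Per-group class-conditional accuracy of the web-interface chat model,
#: by demographic factor -> group -> true class.  Together with the cohort
#: counts these reconstruct the group x correctness contingency tables.
GROUP_ACCURACY: dict[str, dict[str, dict[str, float]]] = {
    "sex": {
        "FEMALE": {"MEL": 0.742, "NV": 0.434, "BKL": 0.239},
        "MALE": {"MEL": 0.754, "NV": 0.519, "BKL": 0.206},
    },
    "age_group": {
        "YOUNG": {"MEL": 0.792, "NV": 0.466, "BKL": 0.267},
        "MIDDLE": {"MEL": 0.765, "NV": 0.479, "BKL": 0.187},
        "SENIOR": {"MEL": 0.734, "NV": 0.493, "BKL": 0.231},
    },
}


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (toward +inf)."""
    return int(math.floor(x + 0.5))


def reconstructed_group_correct_counts(
    factor: str, disease: str
) -> dict[str, tuple[int, int]]:
    """(correct, incorrect) counts per group for the chat model.

    Reconstructed as round-half-up(per-group accuracy x group support);
    this recovers the published per-class diagonal totals exactly
    (e.g. 63 + 83 = 146 correct NV predictions).
    """
    cohort = TEST_COHORT_SEX if factor == "sex" else TEST_COHORT_AGE
    out: dict[str, tuple[int, int]] = {}
    for group, acc in GROUP_ACCURACY[factor].items():
        n = cohort[group][disease]
        correct = round_half_up(acc[disease] * n)
        out[group] = (correct, n - correct)
    return out
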