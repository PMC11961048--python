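"""Confusion matrices and abstention-aware performance metrics."""

import numpy as np
import pytest

import fairskin as fs
from fairskin.fixtures import CLASS_SUPPORTS, CONFUSION_MATRICES
from fairskin.metrics import (
    EmptyStratumError,
    class_conditional_accuracy,
    class_f1,
    class_precision,
    confusion_from_counts,
    confusion_matrix,
    overall_metrics,
    performance_table,
    random_baseline,
)
from fairskin.records import Diagnosis, Predicted, PredictionRecord, Sex

MEL, NV, BKL = Diagnosis.MEL, Diagnosis.NV, Diagnosis.BKL


def test_replayed_fixture_matrix_counts(chatgpt_cm):
    assert chatgpt_cm.row(MEL).tolist() == [251, 76, 3, 5]
    assert chatgpt_cm.total == 972
    assert chatgpt_cm.n_abstained == 18


def test_confusion_matches_brute_force_recount(replayed_records):
    cm = confusion_matrix(replayed_records)
    cls_order = [MEL, NV, BKL]
    pred_order = [Predicted.MEL, Predicted.NV, Predicted.BKL, Predicted.NULL]
    for i, true in enumerate(cls_order):
        for j, pred in enumerate(pred_order):
            brute = sum(
                1
                for r in replayed_records
                if r.true_label is true and r.predicted_label is pred
            )
            assert cm.counts[i, j] == brute
    assert cm.counts.sum() == len(replayed_records)


def test_stratum_matrices_sum_to_overall(replayed_records):
    overall = confusion_matrix(replayed_records)
    for factor in ("sex", "age_group"):
        parts = []
        for level in fs.metrics._FACTOR_LEVELS[factor]:
            try:
                parts.append(confusion_matrix(replayed_records, factor, level).counts)
            except EmptyStratumError:
                pass
        unknown = [
            r
            for r in replayed_records
            if r.group(factor).value == "UNKNOWN"
        ]
        if unknown:
            parts.append(confusion_matrix(unknown).counts)
        assert np.array_equal(sum(parts), overall.counts)


def test_empty_stratum_is_explicit(replayed_records):
    with pytest.raises(EmptyStratumError):
        confusion_matrix(replayed_records, "sex", Sex.UNKNOWN)


def test_class_conditional_accuracy_is_published_recall(chatgpt_cm):
    assert class_conditional_accuracy(chatgpt_cm, MEL) == pytest.approx(251 / 335)
    assert round(class_conditional_accuracy(chatgpt_cm, MEL), 3) == 0.749
    assert round(class_conditional_accuracy(chatgpt_cm, BKL), 2) == 0.22


def test_abstention_scored_incorrect():
    cm = confusion_from_counts(
        {"MEL": (0, 0, 0, 10), "NV": (0, 5, 0, 0), "BKL": (0, 0, 5, 0)}
    )
    assert class_conditional_accuracy(cm, MEL) == 0.0
    om = overall_metrics(cm)
    assert om.accuracy == 0.5 and om.n_abstained == 10


def test_class_f1_matches_published_cell(chatgpt_cm):
    # precision 251/529, recall 251/335
    assert class_precision(chatgpt_cm, MEL) == pytest.approx(251 / 529)
    assert round(class_f1(chatgpt_cm, MEL), 3) == 0.581


def test_perfect_class_f1():
    cm = confusion_from_counts(
        {"MEL": (3, 0, 0, 0), "NV": (0, 3, 0, 0), "BKL": (0, 0, 3, 0)}
    )
    assert class_f1(cm, MEL) == 1.0
    om = overall_metrics(cm)
    assert om.accuracy == om.micro_f1 == 1.0


def test_undefined_f1_flags():
    # zero support and zero predictions of BKL -> undefined (printed N/A)
    cm = confusion_from_counts(
        {"MEL": (2, 1, 0, 0), "NV": (0, 3, 0, 0), "BKL": (0, 0, 0, 0)}
    )
    assert np.isnan(class_f1(cm, BKL))
    # support but nothing predicted -> F1 = 0, not NaN
    cm2 = confusion_from_counts(
        {"MEL": (2, 1, 0, 0), "NV": (0, 3, 0, 0), "BKL": (1, 2, 0, 0)}
    )
    assert class_f1(cm2, BKL) == 0.0


@pytest.mark.parametrize(
    "name, accuracy, micro_f1",
    [
        ("chatgpt4-web", 0.4835, 0.4881),
        ("llava-1.6", 0.578, 0.63),
        ("swin-b", 0.782, 0.782),
        ("model-derm", 0.342, 0.413),
    ],
)
def test_overall_metrics_reproduce_published_rows(all_fixture_cms, name, accuracy, micro_f1):
    om = overall_metrics(all_fixture_cms[name])
    assert om.accuracy == pytest.approx(accuracy, abs=5e-4)
    assert om.micro_f1 == pytest.approx(micro_f1, abs=5e-4)


def test_micro_f1_equals_accuracy_iff_no_abstention(all_fixture_cms):
    for name, cm in all_fixture_cms.items():
        om = overall_metrics(cm)
        consistent = tuple(cm.support) == tuple(cm.counts.sum(axis=1))
        if om.n_abstained == 0 and consistent:
            # e.g. the vision-transformer fixture: both equal 0.782
            assert om.micro_f1 == pytest.approx(om.accuracy)
        elif om.n_abstained > 0:
            assert om.micro_f1 > om.accuracy  # precision pool shrinks
        # micro F1 is bounded by the larger of its two components
        trace = np.trace(cm.counts[:, :3])
        non_null = cm.counts[:, :3].sum()
        assert om.micro_f1 <= max(trace / non_null, om.accuracy) + 1e-12


def test_inconsistent_printed_rows_warn():
    with pytest.warns(UserWarning, match="declared supports"):
        confusion_from_counts(
            CONFUSION_MATRICES["llava-1.6"], stratum="llava", support=CLASS_SUPPORTS
        )


def test_sklearn_oracle_agreement(replayed_records):
    """Precision/recall/F1 agree with scikit-learn on the no-abstention sub-problem."""
    from sklearn.metrics import precision_recall_fscore_support

    kept = [r for r in replayed_records if r.predicted_label is not Predicted.NULL]
    cm = confusion_matrix(kept)
    y_true = [r.true_label.value for r in kept]
    y_pred = [r.predicted_label.value for r in kept]
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=["MEL", "NV", "BKL"], zero_division=np.nan
    )
    for i, d in enumerate((MEL, NV, BKL)):
        assert class_conditional_accuracy(cm, d) == pytest.approx(rec[i])
        assert class_precision(cm, d) == pytest.approx(prec[i])
        assert class_f1(cm, d) == pytest.approx(f1[i])
        assert cm.class_support(d) == support[i]


def test_performance_table_shape_and_order_invariance(replayed_records):
    table = performance_table(replayed_records)
    assert ("all", "All") in set(zip(table["factor"], table["group"]))
    shuffled = list(replayed_records)[::-1]
    table2 = performance_table(shuffled)
    assert table.equals(table2)
    # stratum sizes partition n within each factor
    for factor in ("sex", "age_group"):
        sub = table[table["factor"] == factor]
        # age factor: one record has unknown age and is not in any stratum
        assert sub["n"].sum() in (972, 971)


def test_single_group_equals_all():
    recs = [
        PredictionRecord(f"r{i}", MEL, Predicted.MEL, sex=Sex.FEMALE) for i in range(5)
    ]
    table = performance_table(recs, factors=("sex",)).set_index("group")
    assert table.loc["FEMALE", "acc_All"] == table.loc["All", "acc_All"] == 1.0


def test_random_baseline_contract(test_cohort):
    labels = random_baseline(test_cohort, seed=5)
    assert labels == random_baseline(test_cohort, seed=5)
    assert Predicted.NULL not in labels
    assert set(labels) <= {Predicted.MEL, Predicted.NV, Predicted.BKL}


def test_random_baseline_accuracy_near_one_third(test_cohort):
    """Mean accuracy over replicates stays within 3 MC standard errors of 1/3."""
    import dataclasses

    reps = 200
    n = len(test_cohort)
    accs = []
    for rep in range(reps):
        labels = random_baseline(test_cohort, seed=1000 + rep)
        correct = sum(
            lab.value == r.true_label.value for lab, r in zip(labels, test_cohort)
        )
        accs.append(correct / n)
    se = np.sqrt((1 / 3) * (2 / 3) / (n * reps))
    assert abs(np.mean(accs) - 1 / 3) < 3 * se
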