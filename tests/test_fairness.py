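"""Chi-square battery, multi-group rate gaps and the bias verdict."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import fairskin as fs
from fairskin.fairness import (
    ContingencyTable,
    GroupRates,
    adjudicate_bias,
    aod,
    average_fpr_difference,
    average_tpr_difference,
    build_contingency,
    chi_square_test,
    contingency_from_counts,
    disparate_impact,
    equal_opportunity_gap,
    equalized_odds_gap,
    fairness_table,
    group_rates,
)
from fairskin.fixtures import reconstructed_group_correct_counts
from fairskin.records import Diagnosis, Predicted, PredictionRecord, Sex, ValidationError

MEL, NV, BKL = Diagnosis.MEL, Diagnosis.NV, Diagnosis.BKL


def _rates(tpr, fpr=None, pos=None):
    n = len(tpr)
    return GroupRates(
        MEL,
        [f"g{i}" for i in range(n)],
        np.asarray(tpr, float),
        np.asarray(fpr if fpr is not None else tpr, float),
        np.asarray(pos if pos is not None else tpr, float),
    )


# ---------------------------------------------------------------- chi-square


def test_expected_frequencies_from_margins():
    t = contingency_from_counts({"a": (63, 82), "b": (83, 77)})
    exp = t.expected
    assert np.allclose(exp.sum(axis=0), t.observed.sum(axis=0))
    assert np.allclose(exp.sum(axis=1), t.observed.sum(axis=1))
    assert t.df == 1


def test_reconstructed_sex_mn_table():
    counts = reconstructed_group_correct_counts("sex", "NV")
    assert counts == {"FEMALE": (63, 82), "MALE": (83, 77)}
    res = chi_square_test(contingency_from_counts(counts))
    assert res.p_value == pytest.approx(0.141, abs=1e-3)


@pytest.mark.parametrize(
    "factor, disease, printed_p",
    [
        ("sex", "MEL", 0.814),
        ("sex", "NV", 0.141),
        ("sex", "BKL", 0.475),
        ("age_group", "MEL", 0.738),
        ("age_group", "NV", 0.951),
        ("age_group", "BKL", 0.626),
    ],
)
def test_published_per_disease_p_values(factor, disease, printed_p):
    counts = reconstructed_group_correct_counts(factor, disease)
    res = chi_square_test(contingency_from_counts(counts))
    assert res.p_value == pytest.approx(printed_p, abs=1e-3)


def test_textbook_2x2():
    res = chi_square_test(contingency_from_counts({"a": (10, 20), "b": (20, 10)}))
    assert res.statistic == pytest.approx(20 / 3, abs=1e-9)
    assert res.p_value == pytest.approx(0.0098, abs=5e-4)


def test_observed_equals_expected_gives_zero():
    res = chi_square_test(contingency_from_counts({"a": (10, 10), "b": (20, 20)}))
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_small_expected_warns_but_computes():
    counts = reconstructed_group_correct_counts("age_group", "BKL")
    res = chi_square_test(contingency_from_counts(counts))
    assert res.small_expected_warning and res.min_expected < 5
    assert 0 < res.p_value < 1


def test_zero_expected_cell_is_error():
    with pytest.raises(ValidationError, match="correct"):
        chi_square_test(contingency_from_counts({"a": (0, 10), "b": (0, 20)}))


def test_zero_total_group_dropped_with_warning():
    with pytest.warns(UserWarning, match="dropped"):
        t = contingency_from_counts({"a": (5, 5), "b": (0, 0), "c": (4, 6)})
    assert t.groups == ["a", "c"]
    with pytest.warns(UserWarning), pytest.raises(ValidationError):
        contingency_from_counts({"a": (5, 5), "b": (0, 0)})


@settings(max_examples=200, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(1, 200), st.integers(1, 200)),
        min_size=2,
        max_size=5,
    )
)
def test_chi_square_agrees_with_scipy_oracle(rows):
    table = contingency_from_counts({f"g{i}": r for i, r in enumerate(rows)})
    ours = chi_square_test(table)
    stat, p, df, _ = chi2_contingency(table.observed, correction=False)
    assert ours.statistic == pytest.approx(stat, abs=1e-10)
    assert ours.p_value == pytest.approx(p, abs=1e-10)
    assert ours.df == df


# ------------------------------------------------------------------ rate gaps


def test_single_pair_reduces_to_absolute_difference():
    assert average_tpr_difference(_rates([0.8, 0.6])) == pytest.approx(0.2)
    assert average_fpr_difference(_rates([0.8, 0.6], fpr=[0.1, 0.25])) == pytest.approx(0.15)


def test_three_group_hand_value():
    assert average_tpr_difference(_rates([0.9, 0.8, 0.7])) == pytest.approx(
        (0.1 + 0.2 + 0.1) / 3
    )


def test_aod_is_half_sum():
    r = _rates([0.8, 0.6], fpr=[0.2, 0.1])
    assert aod(r) == pytest.approx(0.5 * (0.2 + 0.1))


def test_identical_groups_are_perfectly_fair():
    r = _rates([0.7, 0.7, 0.7], fpr=[0.2, 0.2, 0.2], pos=[0.4, 0.4, 0.4])
    assert aod(r) == 0.0
    assert equal_opportunity_gap(r) == 0.0
    assert equalized_odds_gap(r) == 0.0
    assert disparate_impact(r) == 1.0


def test_di_hand_ratio():
    assert disparate_impact(_rates([0.5, 0.5], pos=[0.3, 0.6])) == pytest.approx(0.5)


def test_eod_dominates_eop():
    r = _rates([0.8, 0.75], fpr=[0.1, 0.4])
    assert equalized_odds_gap(r) >= equal_opportunity_gap(r)
    assert equalized_odds_gap(r) == pytest.approx(0.3)


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.floats(0, 1), min_size=2, max_size=5),
    st.randoms(use_true_random=False),
)
def test_gap_metrics_bounded_and_permutation_invariant(tpr, rnd):
    fpr = list(reversed(tpr))
    r = _rates(tpr, fpr=fpr, pos=[0.5] * len(tpr))
    a, eop, eod = aod(r), equal_opportunity_gap(r), equalized_odds_gap(r)
    for v in (a, eop, eod):
        assert 0.0 <= v <= 1.0
    perm = list(range(len(tpr)))
    rnd.shuffle(perm)
    rp = _rates([tpr[i] for i in perm], fpr=[fpr[i] for i in perm], pos=[0.5] * len(tpr))
    assert aod(rp) == pytest.approx(a)
    assert equal_opportunity_gap(rp) == pytest.approx(eop)
    assert equalized_odds_gap(rp) == pytest.approx(eod)
    if len(set(tpr)) == 1 == len(set(fpr)):
        assert a == 0.0


def test_monotone_in_departing_tpr():
    base = [0.6, 0.6, 0.6]
    prev = average_tpr_difference(_rates(base))
    for bump in (0.05, 0.1, 0.2):
        cur = average_tpr_difference(_rates([0.6 + bump, 0.6, 0.6]))
        assert cur > prev
        prev = cur


def test_group_rates_match_brute_force_conditionals():
    # hand-built 12-record fixture, two sex groups
    recs = []
    spec = [
        ("F", MEL, "MEL"), ("F", MEL, "NV"), ("F", NV, "NV"), ("F", NV, "MEL"),
        ("F", BKL, "BKL"), ("F", BKL, "MEL"),
        ("M", MEL, "MEL"), ("M", MEL, "MEL"), ("M", NV, "NULL"), ("M", NV, "NV"),
        ("M", BKL, "NV"), ("M", BKL, "BKL"),
    ]
    for i, (sex, true, pred) in enumerate(spec):
        recs.append(
            PredictionRecord(
                f"r{i}", true, Predicted(pred),
                sex=Sex.FEMALE if sex == "F" else Sex.MALE,
            )
        )
    rates = group_rates(recs, "sex", MEL)
    # brute force: F positives = 2 (1 predicted MEL), F negatives = 4 (2 predicted MEL)
    assert rates.tpr.tolist() == pytest.approx([1 / 2, 2 / 2])
    assert rates.fpr.tolist() == pytest.approx([2 / 4, 0 / 4])
    # NULL never counts as a positive prediction
    rates_nv = group_rates(recs, "sex", NV)
    assert rates_nv.tpr.tolist() == pytest.approx([1 / 2, 1 / 2])


def test_group_identical_behavior_gives_equal_rates(test_cohort):
    profile = fs.load_fixture_profile("swin-b")
    recs = fs.simulate_predictions(test_cohort, profile, seed=3)
    rates = group_rates(recs, "sex", MEL)
    # same generative process per group: rates close, AOD near 0
    assert abs(rates.tpr[0] - rates.tpr[1]) < 0.2
    assert aod(rates) < 0.15


# ----------------------------------------------------------------- adjudication


def test_verdict_reproduces_published_rows():
    not_biased = {"MEL": 0.814, "NV": 0.141, "BKL": 0.475, "All": 0.545}
    verdict, scopes = adjudicate_bias(not_biased, alpha=0.05)
    assert not verdict and scopes == []
    biased = {"MEL": 0.294, "NV": 0.005, "BKL": 0.337, "All": 0.06}
    verdict, scopes = adjudicate_bias(biased, alpha=0.05)
    assert verdict and scopes == ["NV"]


def test_alpha_zero_never_biased():
    verdict, _ = adjudicate_bias({"MEL": 1e-12}, alpha=0.0)
    assert not verdict


def test_fairness_table_end_to_end(replayed_records):
    summaries = fairness_table(replayed_records)
    assert [s.factor for s in summaries] == ["sex", "age_group"]
    for s in summaries:
        frame = s.per_class
        assert list(frame.index) == ["MEL", "NV", "BKL", "All"]
        assert ((frame["p_value"] >= 0) & (frame["p_value"] <= 1)).all()
        assert (frame["aod"] >= 0).all()
        assert s.biased == any(p < 0.05 for p in frame["p_value"])
    # permutation invariance of the full report
    shuffled = list(replayed_records)[::-1]
    again = fairness_table(shuffled)
    for a, b in zip(summaries, again):
        assert a.per_class.equals(b.per_class) and a.biased == b.biased


def test_build_contingency_excludes_unknown_and_scopes_classes(replayed_records):
    t_all = build_contingency(replayed_records, "age_group", "all")
    assert t_all.observed.sum() == 971  # one record has unknown age
    t_mel = build_contingency(replayed_records, "age_group", MEL)
    assert t_mel.observed.sum() == 335
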