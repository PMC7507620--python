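"""Vocabulary building, IF/ICF/IFICF weighting, encoders, imputation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from etsm import (
    CombinationVocabulary,
    assemble,
    build_vocabulary,
    ificf_weights,
    indicator_frequency,
    inverse_cohort_frequency,
)
from etsm.cohort import PredictionSample
from etsm.features import (
    MedicationSequence,
    bool_drug_features,
    explicit_features,
    impute,
    medication_sequence,
    times_drug_features,
)

from conftest import make_record


def ificf_oracle(day_sets_per_patient):
    """Brute-force dictionary-counting evaluation of the IFICF weights.

    ``day_sets_per_patient``: list over patients of lists of per-day drug
    sets.  Returns (sorted combination tuples, rows), computing
    IF = f_{c,s} / len(s) and ICF = ln(N / (1 + n_c)) directly.
    """
    canon = lambda s: tuple(sorted(s))
    combos = sorted({canon(s) for seq in day_sets_per_patient for s in seq})
    n = len(day_sets_per_patient)
    n_c = {
        c: sum(any(canon(s) == c for s in seq) for seq in day_sets_per_patient)
        for c in combos
    }
    rows = []
    for seq in day_sets_per_patient:
        row = []
        for c in combos:
            if not seq:
                row.append(0.0)
                continue
            f = sum(canon(s) == c for s in seq)
            row.append((f / len(seq)) * math.log(n / (1 + n_c[c])))
        rows.append(row)
    return combos, np.array(rows)


def records_from_day_sets(day_sets_per_patient):
    records, points = [], {}
    for i, seq in enumerate(day_sets_per_patient):
        pid = f"q{i}"
        records.append(
            make_record(pid, 12, daily_drugs={d: set(s) for d, s in enumerate(seq) if s})
        )
        points[pid] = 12
    return records, points


# ---------------------------------------------------------------------------
# vocabulary


def test_vocabulary_canonicalizes_and_counts_patients_not_days():
    # patient A uses {x,y} on two days (listed in both orders); B uses {y}
    records, points = records_from_day_sets([[{"x", "y"}, {"y", "x"}], [{"y"}]])
    vocab = build_vocabulary(records, points)
    assert vocab.combinations == [("x", "y"), ("y",)]
    assert vocab.doc_freq == {0: 1, 1: 1}
    assert vocab.n_corpus_patients == 2


def test_vocabulary_repeated_combo_counts_once():
    records, points = records_from_day_sets([[{"a"}] * 5, [{"b"}]])
    vocab = build_vocabulary(records, points)
    assert vocab.doc_freq[vocab.combo_id(("a",))] == 1


def test_vocabulary_empty_and_order_invariance():
    records, points = records_from_day_sets([[], []])
    assert len(build_vocabulary(records, points)) == 0

    day_sets = [[{"a"}, {"a", "b"}], [{"b"}], [{"a", "b"}, {"c"}]]
    recs, pts = records_from_day_sets(day_sets)
    v1 = build_vocabulary(recs, pts)
    v2 = build_vocabulary(list(reversed(recs)), pts)
    assert v1.combinations == v2.combinations
    assert v1.doc_freq == v2.doc_freq


def test_vocabulary_json_round_trip():
    recs, pts = records_from_day_sets([[{"a"}, {"a", "b"}], [{"b"}]])
    vocab = build_vocabulary(recs, pts)
    back = CombinationVocabulary.from_json(vocab.to_json())
    assert back.combinations == vocab.combinations
    assert back.doc_freq == vocab.doc_freq
    assert back.combo_id(("a", "b")) == vocab.combo_id(("a", "b"))


def test_sequence_visibility_stops_at_predictive_point():
    rec = make_record("s", 6, daily_drugs={0: {"a"}, 2: {"b"}, 5: {"c"}})
    assert medication_sequence(rec, 2).combos == (("a",), ("b",))
    assert medication_sequence(rec, 6).combos == (("a",), ("b",), ("c",))


# ---------------------------------------------------------------------------
# IF / ICF / IFICF


def test_indicator_frequency_worked_examples():
    c1, c2 = ("a",), ("b",)
    s = MedicationSequence("p", (c1, c1, c2))
    assert indicator_frequency(c1, s) == pytest.approx(2 / 3)
    assert indicator_frequency(c2, s) == pytest.approx(1 / 3)
    assert indicator_frequency(("z",), s) == 0.0
    assert indicator_frequency(c1, MedicationSequence("p", (c1,))) == 1.0


def test_icf_worked_examples():
    vocab = CombinationVocabulary(
        combinations=[("a",), ("b",)], doc_freq={0: 4, 1: 10}, n_corpus_patients=10
    )
    assert inverse_cohort_frequency(("a",), vocab) == pytest.approx(math.log(2))
    # combination present in every sequence: negative weight
    assert inverse_cohort_frequency(("b",), vocab) == pytest.approx(math.log(10 / 11))
    # unseen combination behaves as n_c = 0
    assert inverse_cohort_frequency(("z",), vocab) == pytest.approx(math.log(10))
    one = CombinationVocabulary([("a",)], {0: 0}, 1)
    assert inverse_cohort_frequency(("a",), one) == 0.0


def test_ificf_worked_example():
    c1, c2 = ("a",), ("b",)
    vocab = CombinationVocabulary([c1, c2], {0: 4, 1: 9}, 10)
    row = ificf_weights(MedicationSequence("p", (c1, c1, c2)), vocab)
    assert row[0] == pytest.approx((2 / 3) * math.log(2))
    assert row[1] == pytest.approx(0.0)  # ln(10/10) = 0
    assert (ificf_weights(MedicationSequence("p", ()), vocab) == 0).all()


def test_ificf_matches_brute_force_on_random_corpora():
    rng = np.random.default_rng(3)
    drugs = np.array(list("abcde"))
    for _ in range(500):
        n_pat = int(rng.integers(1, 21))
        day_sets = []
        for _ in range(n_pat):
            n_days = int(rng.integers(0, 11))
            day_sets.append(
                [
                    set(rng.choice(drugs, size=rng.integers(1, 6), replace=False))
                    for _ in range(n_days)
                ]
            )
        combos, expected = ificf_oracle(day_sets)
        records, points = records_from_day_sets(day_sets)
        vocab = build_vocabulary(records, points)
        assert vocab.combinations == combos
        for rec, want in zip(records, expected):
            got = ificf_weights(
                medication_sequence(rec, points[rec.patient_id]), vocab
            )
            np.testing.assert_allclose(got, want, atol=1e-12)


def test_if_normalization_sums_to_one(small_cohort):
    records, _, _ = small_cohort
    points = {r.patient_id: r.stay_days for r in records}
    vocab = build_vocabulary(records, points)
    checked = 0
    for rec in records:
        seq = medication_sequence(rec, points[rec.patient_id])
        if len(seq) == 0:
            continue
        total = sum(indicator_frequency(c, seq) for c in vocab.combinations)
        assert total == pytest.approx(1.0, abs=1e-12)
        checked += 1
    assert checked > 0


def test_icf_monotone_in_doc_freq():
    vocab = CombinationVocabulary(
        combinations=[(c,) for c in "abcdef"],
        doc_freq={k: k for k in range(6)},
        n_corpus_patients=20,
    )
    vals = [inverse_cohort_frequency((c,), vocab) for c in "abcdef"]
    assert all(x > y for x, y in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# bool / times encoders


def test_bool_and_times_drug_features():
    rec = make_record(
        "p", 6, daily_drugs={0: {"d1"}, 1: {"d1", "d2"}, 3: {"d1"}, 6: {"d3"}}
    )
    inventory = ["d1", "d2", "d3"]
    times = times_drug_features(rec, 4, inventory)
    boolean = bool_drug_features(rec, 4, inventory)
    assert times.tolist() == [3.0, 1.0, 0.0]
    assert boolean.tolist() == [1.0, 1.0, 0.0]


def test_bool_is_indicator_of_times(small_cohort):
    records, _, _ = small_cohort
    inventory = sorted({d for r in records for s in r.daily_drugs.values() for d in s})
    for rec in records[:40]:
        pp = rec.stay_days
        t = times_drug_features(rec, pp, inventory)
        b = bool_drug_features(rec, pp, inventory)
        np.testing.assert_array_equal(b, (t > 0).astype(float))


def test_no_drugs_gives_zero_rows():
    rec = make_record("p", 3)
    assert bool_drug_features(rec, 3, ["d1"]).tolist() == [0.0]
    assert times_drug_features(rec, 3, ["d1"]).tolist() == [0.0]


# ---------------------------------------------------------------------------
# explicit features and imputation


def test_explicit_features_extraction():
    rec = make_record("p", 5, measurements={"hr": [(0, 80.0), (3, 95.0)]})
    row = explicit_features(rec, 3, ["hr", "sbp"])
    # layout: [hr@adm, sbp@adm, hr@pp, sbp@pp]
    assert row[0] == 80.0 and row[2] == 95.0
    assert np.isnan(row[1]) and np.isnan(row[3])
    same = explicit_features(rec, 0, ["hr"])
    assert same[0] == same[1] == 80.0  # predictive point on admission day


def _one_sample_matrix(rec, pp, variables):
    sample = PredictionSample(rec.patient_id, False, pp, 24)
    matrix = assemble([sample], {rec.patient_id: rec}, variables, encoder="none")
    return matrix, [sample]


def test_impute_nearest_prefers_earlier_on_tie():
    rec = make_record("p", 4, measurements={"hr": [(0, 5.0), (2, 7.0)]})
    matrix, samples = _one_sample_matrix(rec, 1, ["hr"])
    # the predictive-point slot (day 1) is equidistant from days 0 and 2
    assert np.isnan(matrix.values.iloc[0, 1])
    filled = impute(matrix, {"p": rec}, samples, [True])
    assert filled.values.iloc[0, 1] == 5.0


def test_impute_falls_back_to_derivation_median():
    recs = {
        "a": make_record("a", 3, measurements={"hr": [(0, 6.0)]}),
        "b": make_record("b", 3, measurements={"hr": [(0, 7.0)]}),
        "c": make_record("c", 3, measurements={}),
    }
    samples = [PredictionSample(p, False, 2, 24) for p in ("a", "b", "c")]
    matrix = assemble(samples, recs, ["hr"], encoder="none")
    filled = impute(matrix, recs, samples, [True, True, False])
    # patient c never has hr: both slots get the derivation median (6.5)
    assert filled.values.loc["c"].tolist() == [6.5, 6.5]


def test_impute_identity_when_complete_and_never_alters_observed():
    rec = make_record("p", 2, measurements={"hr": [(0, 9.0), (2, 8.0)]})
    matrix, samples = _one_sample_matrix(rec, 2, ["hr"])
    filled = impute(matrix, {"p": rec}, samples, [True])
    assert filled.values.equals(matrix.values)


def test_impute_all_missing_column_warns_and_zero_fills():
    rec = make_record("p", 2)
    matrix, samples = _one_sample_matrix(rec, 2, ["hr"])
    with pytest.warns(UserWarning, match="entirely missing"):
        filled = impute(matrix, {"p": rec}, samples, [True])
    assert filled.values.iloc[0].tolist() == [0.0, 0.0]


# ---------------------------------------------------------------------------
# assembly


def test_assemble_column_counts_and_determinism():
    recs, pts = records_from_day_sets([[{"a"}, {"a", "b"}], [{"b"}]])
    for rec in recs:
        rec.measurements = {"hr": [(0, 80.0)], "sbp": [(0, 120.0)]}
    samples = [PredictionSample(r.patient_id, False, 5, 24) for r in recs]
    by_id = {r.patient_id: r for r in recs}
    vocab = build_vocabulary(recs, pts)

    ex = assemble(samples, by_id, ["hr", "sbp"], encoder="none")
    assert ex.n_features == 4
    full = assemble(samples, by_id, ["hr", "sbp"], encoder="ificf", vocab=vocab)
    assert full.n_features == 4 + len(vocab)
    again = assemble(samples, by_id, ["hr", "sbp"], encoder="ificf", vocab=vocab)
    assert full.values.equals(again.values)
    boolm = assemble(samples, by_id, ["hr", "sbp"], encoder="bool",
                     drug_inventory=["a", "b"])
    assert boolm.n_features == 4 + 2
    assert boolm.column_groups.count("implicit") == 2


def test_assemble_rejects_bad_encoder_configs():
    recs, _ = records_from_day_sets([[{"a"}]])
    samples = [PredictionSample("q0", False, 1, 24)]
    with pytest.raises(ValueError, match="encoder"):
        assemble(samples, {"q0": recs[0]}, [], encoder="nope")
    with pytest.raises(ValueError, match="Vocabulary"):
        assemble(samples, {"q0": recs[0]}, [], encoder="ificf")
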