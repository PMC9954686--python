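"""Evaluation machinery: reports, voting, aggregation, confusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slicevit.evaluate import (
    aggregate_repetitions,
    classification_report,
    normalized_confusion,
    subject_report,
    vote_majority,
)
from slicevit.train import SlicePrediction


def sp(sid, true, pred, probs=None, labels=("AD", "HC", "MCI"), z=0, t=0):
    if probs is None:
        probs = np.array([1.0 if lab == pred else 0.0 for lab in labels])
    return SlicePrediction(subject_id=sid, z=z, t=t, true_label=true,
                           predicted_label=pred, probabilities=np.asarray(probs),
                           labels=labels)


# -- classification report ---------------------------------------------------

def test_perfect_predictions():
    rep = classification_report(["A", "B", "A"], ["A", "B", "A"])
    assert rep.accuracy == 1.0
    for avg in (rep.macro_avg, rep.weighted_avg):
        assert all(v == 1.0 for v in avg.values())


def test_worked_two_class_example():
    """truth [A,A,B,B], pred [A,B,B,B]: hand-computed confusion-table oracle."""
    rep = classification_report(["A", "B", "B", "B"], ["A", "A", "B", "B"])
    assert rep.per_class["A"]["precision"] == pytest.approx(1.0)
    assert rep.per_class["A"]["recall"] == pytest.approx(0.5)
    assert rep.per_class["A"]["f1"] == pytest.approx(2 / 3)
    assert rep.per_class["B"]["precision"] == pytest.approx(2 / 3)
    assert rep.per_class["B"]["recall"] == pytest.approx(1.0)
    assert rep.per_class["B"]["f1"] == pytest.approx(0.8)
    assert rep.accuracy == pytest.approx(0.75)
    assert rep.weighted_avg["f1"] == pytest.approx(11 / 15)


def test_balanced_classes_weighted_equals_macro():
    rep = classification_report(["A", "B", "A", "B"], ["A", "A", "B", "B"])
    for m in ("precision", "recall", "f1"):
        assert rep.weighted_avg[m] == pytest.approx(rep.macro_avg[m])


def test_never_predicted_class_gets_zero_precision():
    rep = classification_report(["A", "A", "A"], ["A", "B", "A"])
    assert rep.per_class["B"]["precision"] == 0.0
    assert rep.per_class["B"]["recall"] == 0.0


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        classification_report(["A"], ["A", "B"])


@given(st.lists(st.sampled_from(["A", "B", "C"]), min_size=1, max_size=40),
       st.integers(0, 5))
@settings(max_examples=40, deadline=None)
def test_accuracy_equals_weighted_recall(trues, seed):
    """Algebraic identity, asserted to 1e-12."""
    rng = np.random.default_rng(seed)
    preds = list(rng.choice(["A", "B", "C"], size=len(trues)))
    rep = classification_report(preds, trues)
    assert abs(rep.accuracy - rep.weighted_avg["recall"]) < 1e-12


def test_report_matches_sklearn_oracle():
    """Dual-route check against scikit-learn on random labels."""
    sklearn = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(7)
    trues = rng.choice(["A", "B", "C"], size=60)
    preds = rng.choice(["A", "B", "C"], size=60)
    rep = classification_report(preds, trues)
    ref = sklearn.classification_report(trues, preds, output_dict=True,
                                        zero_division=0)
    for lab in "ABC":
        assert rep.per_class[lab]["precision"] == pytest.approx(ref[lab]["precision"])
        assert rep.per_class[lab]["recall"] == pytest.approx(ref[lab]["recall"])
        assert rep.per_class[lab]["f1"] == pytest.approx(ref[lab]["f1-score"])
    assert rep.weighted_avg["f1"] == pytest.approx(ref["weighted avg"]["f1-score"])
    assert rep.macro_avg["f1"] == pytest.approx(ref["macro avg"]["f1-score"])
    assert rep.accuracy == pytest.approx(ref["accuracy"])


# -- vote for majority -------------------------------------------------------

def test_vote_fraction_two_thirds():
    preds = [sp("s1", "AD", "AD"), sp("s1", "AD", "AD"), sp("s1", "AD", "HC")]
    [agg] = vote_majority(preds)
    assert agg.predicted_label == "AD"
    assert agg.class_vote_fractions["AD"] == pytest.approx(2 / 3)
    assert sum(agg.class_vote_fractions.values()) == pytest.approx(1.0)


def test_vote_tie_breaks_lexicographic():
    preds = [sp("s1", "HC", "AD"), sp("s1", "HC", "HC")]
    [agg] = vote_majority(preds)
    assert agg.predicted_label == "AD"


def test_single_slice_subjects_reduce_to_slice_report():
    rng = np.random.default_rng(0)
    labels = ("AD", "HC", "MCI")
    preds = [sp(f"s{i}", rng.choice(labels), rng.choice(labels), z=0)
             for i in range(30)]
    slice_rep = classification_report([p.predicted_label for p in preds],
                                      [p.true_label for p in preds])
    subj_rep = subject_report(vote_majority(preds))
    assert subj_rep.accuracy == pytest.approx(slice_rep.accuracy)
    assert subj_rep.weighted_avg == pytest.approx(slice_rep.weighted_avg)


def test_vote_dominance_property():
    """>= half of every subject's slices correct -> subject accuracy 1
    (strict majority)."""
    preds = []
    for i, true in enumerate(["AD", "HC", "MCI"] * 3):
        sid = f"s{i}"
        wrong = "AD" if true != "AD" else "HC"
        preds += [sp(sid, true, true, z=z) for z in range(3)]
        preds += [sp(sid, true, wrong, z=10 + z) for z in range(2)]
    rep = subject_report(vote_majority(preds))
    assert rep.accuracy == 1.0


def test_vote_probability_averaging_flag():
    probs_a = np.array([0.4, 0.6, 0.0])
    probs_b = np.array([0.9, 0.1, 0.0])
    preds = [sp("s1", "AD", "HC", probs=probs_a), sp("s1", "AD", "AD", probs=probs_b)]
    [hard] = vote_majority(preds)
    assert hard.class_vote_fractions["AD"] == pytest.approx(0.5)
    [soft] = vote_majority(preds, use_probabilities=True)
    assert soft.class_vote_fractions["AD"] == pytest.approx(0.65)
    assert soft.predicted_label == "AD"


def test_vote_empty_rejected():
    with pytest.raises(ValueError, match="no slice predictions"):
        vote_majority([])


# -- repetition aggregation --------------------------------------------------

def reports(values):
    return [classification_report(["A"] * 10, ["A"] * 10) for _ in values]


def test_identical_reports_zero_std():
    rep = classification_report(["A", "B"], ["A", "B"])
    summary = aggregate_repetitions([rep, rep, rep])
    assert all(s == 0.0 for s in summary.stds.values())
    assert summary.render("f1") == "1 ± 0"


def test_mean_arithmetic():
    reps = []
    for acc_target in (0.96, 0.97, 0.98):
        n_correct = round(acc_target * 100)
        preds = ["A"] * n_correct + ["B"] * (100 - n_correct)
        reps.append(classification_report(preds, ["A"] * 100))
    summary = aggregate_repetitions(reps)
    assert summary.means["f1"] == pytest.approx(
        np.mean([r.weighted_avg["f1"] for r in reps]))
    assert summary.means["accuracy"] == pytest.approx(0.97)


def test_single_report_std_zero():
    rep = classification_report(["A", "B"], ["B", "B"])
    summary = aggregate_repetitions([rep])
    assert summary.stds["accuracy"] == 0.0
    assert summary.means["accuracy"] == rep.accuracy


def test_population_std_convention():
    reps = []
    for p in (["A", "A"], ["A", "B"]):
        reps.append(classification_report(p, ["A", "A"]))
    summary = aggregate_repetitions(reps)
    accs = [r.accuracy for r in reps]
    assert summary.stds["accuracy"] == pytest.approx(np.std(accs, ddof=0))


def test_permutation_invariance():
    reps = [classification_report(p, ["A", "A", "B"])
            for p in (["A", "A", "B"], ["A", "B", "B"], ["B", "A", "B"])]
    a = aggregate_repetitions(reps)
    b = aggregate_repetitions(reps[::-1])
    assert a.means == b.means and a.stds == b.stds


def test_mixed_levels_rejected():
    a = classification_report(["A"], ["A"], level="slice")
    b = classification_report(["A"], ["A"], level="subject")
    with pytest.raises(ValueError, match="mixed"):
        aggregate_repetitions([a, b])


# -- confusion matrices ------------------------------------------------------

def test_confusion_perfect_identity():
    m = normalized_confusion(["A", "B", "C"], ["A", "B", "C"])
    assert np.array_equal(m.to_numpy(), np.eye(3))


def test_confusion_rows_sum_to_one():
    rng = np.random.default_rng(3)
    trues = rng.choice(["A", "B", "C"], size=50)
    preds = rng.choice(["A", "B", "C"], size=50)
    m = normalized_confusion(preds, trues)
    assert np.allclose(m.to_numpy().sum(axis=1), 1.0)


def test_confusion_worked_example():
    m = normalized_confusion(["A", "B", "B"], ["A", "A", "B"])
    assert np.allclose(m.to_numpy(), [[0.5, 0.5], [0.0, 1.0]])


def test_confusion_empty_true_class_zero_row():
    m = normalized_confusion(["A", "A"], ["A", "A"], labels=["A", "B"])
    assert np.allclose(m.loc["B"].to_numpy(), 0.0)
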