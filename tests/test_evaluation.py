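import numpy as np
import pytest

from tripletknn.evaluation import (
    FoldReport,
    confusion,
    fold_average,
    image_metrics,
    patient_fold_grid,
    patient_results,
    patient_score,
    pla,
)

from .conftest import make_prediction_set
from .oracles import auc_by_pairs


# ---------------------------------------------------------------- patient score

def test_patient_score_count_ratio():
    pset = make_prediction_set([
        ("i1", "benign", "benign"),
        ("i2", "benign", "benign"),
        ("i3", "benign", "benign"),
        ("i4", "benign", "malignant"),
    ])
    r = patient_score(pset)
    assert r.patient_score == pytest.approx(0.75)
    assert (r.n_images, r.n_correct) == (4, 3)
    assert r.assigned_label == "benign"


@pytest.mark.parametrize("pred, expected", [("benign", 1.0), ("malignant", 0.0)])
def test_patient_score_extremes(pred, expected):
    pset = make_prediction_set([(f"i{j}", "benign", pred) for j in range(5)])
    assert patient_score(pset).patient_score == expected


def test_patient_assignment_tie_goes_malignant():
    pset = make_prediction_set([
        ("i1", "benign", "benign"),
        ("i2", "benign", "benign"),
        ("i3", "benign", "malignant"),
        ("i4", "benign", "malignant"),
    ])
    r = patient_score(pset)
    assert r.assigned_label == "malignant"
    assert r.patient_score == pytest.approx(0.5)
    assert r.fraction_malignant == pytest.approx(0.5)


def test_mixed_true_labels_rejected():
    pset = make_prediction_set([
        ("i1", "benign", "benign"),
        ("i2", "malignant", "benign"),
    ])
    with pytest.raises(ValueError, match="mixed"):
        patient_score(pset)
    with pytest.raises(ValueError, match="at least one"):
        patient_score([])


# ---------------------------------------------------------------- PLA

def test_pla_is_mean_of_patient_scores():
    pset = make_prediction_set([
        ("a1", "benign", "benign"), ("a2", "benign", "benign"),
        ("b1", "malignant", "benign"), ("b2", "malignant", "malignant"),
    ])
    results = patient_results(pset, ["A", "A", "B", "B"])
    assert pla(results) == pytest.approx((1.0 + 0.5) / 2)


def test_pla_weights_patients_not_images():
    """Patient A: 10/10 correct; patient B: 0/1 -> PLA 0.5 although image
    accuracy is 10/11."""
    rows = [(f"a{j}", "benign", "benign") for j in range(10)]
    rows.append(("b0", "malignant", "benign"))
    pset = make_prediction_set(rows)
    results = patient_results(pset, ["A"] * 10 + ["B"])
    assert pla(results) == pytest.approx(0.5)
    assert image_metrics(pset)["image_accuracy"] == pytest.approx(10 / 11)


def test_pla_equals_image_accuracy_for_uniform_patient_sizes(rng):
    rows, patients = [], []
    for pi in range(6):
        truth = "benign" if pi % 2 else "malignant"
        for j in range(4):  # same number of images per patient
            pred = truth if rng.random() < 0.7 else (
                "malignant" if truth == "benign" else "benign")
            rows.append((f"p{pi}i{j}", truth, pred))
            patients.append(f"P{pi}")
    pset = make_prediction_set(rows)
    assert pla(patient_results(pset, patients)) == pytest.approx(
        image_metrics(pset)["image_accuracy"]
    )


def test_pla_constant_scores_and_empty():
    assert pla([0.3, 0.3, 0.3]) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        pla([])


# ---------------------------------------------------------------- image metrics

def test_metrics_closed_form_from_confusion_counts():
    """TP=3 FP=1 FN=1 TN=5 with benign as positive."""
    rows = (
        [(f"tp{j}", "benign", "benign") for j in range(3)]
        + [("fp0", "malignant", "benign")]
        + [("fn0", "benign", "malignant")]
        + [(f"tn{j}", "malignant", "malignant") for j in range(5)]
    )
    m = image_metrics(make_prediction_set(rows))
    assert m["precision"] == pytest.approx(0.75)
    assert m["recall"] == pytest.approx(0.75)
    assert m["f1"] == pytest.approx(0.75)
    assert m["image_accuracy"] == pytest.approx(8 / 10)
    C = confusion(make_prediction_set(rows))
    np.testing.assert_array_equal(C, [[3, 1], [1, 5]])


def test_all_correct_gives_perfect_metrics():
    rows = [("i1", "benign", "benign"), ("i2", "malignant", "malignant")]
    m = image_metrics(make_prediction_set(rows))
    for name in ("image_accuracy", "precision", "recall", "f1", "auc"):
        assert m[name] == pytest.approx(1.0)


def test_auc_matches_pairwise_rank_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(5, 100))
        truths = ["benign" if b else "malignant" for b in rng.integers(0, 2, n)]
        if len(set(truths)) < 2:
            continue
        scores = rng.integers(0, 4, n) / 3  # coarse scores force ties
        rows = [
            (f"i{j}", truths[j], "benign" if scores[j] > 0.5 else "malignant",
             float(scores[j]))
            for j in range(n)
        ]
        m = image_metrics(make_prediction_set(rows))
        expect = auc_by_pairs([t == "benign" for t in truths], list(scores))
        assert m["auc"] == pytest.approx(expect)


def test_single_class_truth_reports_missing_auc():
    rows = [("i1", "benign", "benign"), ("i2", "benign", "malignant")]
    with pytest.warns(UserWarning, match="AUC undefined"):
        m = image_metrics(make_prediction_set(rows))
    assert m["auc"] is None


def test_metrics_invariant_to_row_permutation(rng):
    rows = [
        (f"i{j}", t, p, s)
        for j, (t, p, s) in enumerate(
            zip(
                ["benign", "malignant"] * 6,
                ["benign", "benign", "malignant"] * 4,
                rng.random(12),
            )
        )
    ]
    m1 = image_metrics(make_prediction_set(rows))
    order = rng.permutation(len(rows))
    m2 = image_metrics(make_prediction_set([rows[i] for i in order]))
    assert m1 == m2


# ---------------------------------------------------------------- aggregation

def _fold(idx, rows, patients):
    return FoldReport.from_predictions(idx, make_prediction_set(rows), patients)


def test_fold_average_of_identical_folds_has_zero_sd():
    rows = [("i1", "benign", "benign"), ("i2", "malignant", "malignant"),
            ("i3", "malignant", "benign")]
    patients = ["A", "B", "B"]
    rep = fold_average([_fold(1, rows, patients), _fold(2, rows, patients)])
    assert rep.pla_sd == 0.0
    assert rep.pla_mean == pytest.approx(_fold(1, rows, patients).pla)
    np.testing.assert_array_equal(rep.confusion_mean, _fold(1, rows, patients).confusion)


def test_fold_average_mean_and_sample_sd():
    f1 = _fold(1, [("i1", "benign", "benign"), ("i2", "malignant", "benign")], ["A", "B"])
    f2 = _fold(2, [("i1", "benign", "benign"), ("i2", "malignant", "malignant")], ["A", "B"])
    assert (f1.pla, f2.pla) == (0.5, 1.0)
    rep = fold_average([f1, f2])
    assert rep.pla_mean == pytest.approx(0.75)
    assert rep.pla_sd == pytest.approx(np.std([0.5, 1.0], ddof=1))
    # averaged confusion entries sum to the mean test-set size
    assert rep.confusion_mean.sum() == pytest.approx(2.0)


def test_fold_average_rejects_mismatched_metric_sets():
    f1 = _fold(1, [("i1", "benign", "benign"), ("i2", "malignant", "malignant")], ["A", "B"])
    f2 = _fold(2, [("i1", "benign", "benign"), ("i2", "malignant", "malignant")], ["A", "B"])
    f2.metrics = {"image_accuracy": 1.0}
    with pytest.raises(ValueError, match="mismatched"):
        fold_average([f1, f2])
    with pytest.raises(ValueError, match="at least one"):
        fold_average([])


def test_patient_fold_grid_cells_and_stability():
    f1 = _fold(1, [("i1", "benign", "malignant"), ("i2", "malignant", "malignant")],
               ["A", "B"])
    f2 = _fold(2, [("i1", "benign", "benign")], ["A"])
    grid = patient_fold_grid([f1, f2])
    assert grid.fraction.loc["A", 1] == pytest.approx(1.0)   # all labelled malignant
    assert grid.fraction.loc["A", 2] == pytest.approx(0.0)
    assert np.isnan(grid.fraction.loc["B", 2])               # absent from fold 2
    assert grid.unstable_patients() == ["A"]                 # flips across folds
    # benign patients listed before malignant ones
    assert list(grid.fraction.index) == ["A", "B"]


def test_report_files_roundtrip(tmp_path):
    f1 = _fold(1, [("i1", "benign", "benign"), ("i2", "malignant", "malignant")], ["A", "B"])
    rep = fold_average([f1])
    rep.write(tmp_path)
    import pandas as pd

    metrics = pd.read_csv(tmp_path / "metrics.csv")
    assert set(metrics["metric"]) >= {"pla", "image_accuracy", "f1"}
    conf = pd.read_csv(tmp_path / "confusion_mean.csv", index_col=0)
    assert conf.to_numpy().sum() == pytest.approx(2.0)
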