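"""Patient-level and image-level evaluation of fold predictions.

Histopathology classification is assessed per *patient*, not per image: the
clinically meaningful unit is the patient, and patients contribute very
different numbers of patches. For one patient P with N_P test images of
which N_rec are correctly classified,

    PatientScore(P) = N_rec / N_P

and the Patient-Level Accuracy of a fold is the unweighted mean of the
patient scores,

    PLA = (1/|patients|) * sum_P PatientScore(P).

PLA equals plain image accuracy exactly when every patient contributes the
same number of test images and diverges otherwise — one prolific, easy
patient cannot mask failures on a rare one.

Image-level metrics (accuracy, precision, recall, F1, AUC) treat the
**benign class as positive**; AUC uses the k-NN benign-neighbour fraction as
the score, with the rank-based (Mann-Whitney, midrank ties) formulation.
Per-fold results are aggregated as mean +/- sample standard deviation
(ddof=1) and element-wise averaged confusion matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .knn import POSITIVE_CLASS, TIE_PREDICTION, PredictionSet

CLASS_ORDER = ("benign", "malignant")   # confusion-matrix row/col order (rows = truth)
METRIC_NAMES = ("image_accuracy", "precision", "recall", "f1", "auc", "pla")


@dataclass(frozen=True)
class PatientResult:
    """Per-patient tally of one fold's test predictions."""

    patient_id: str
    true_label: str
    n_images: int
    n_correct: int
    assigned_label: str
    fraction_malignant: float   # of this patient's images labelled malignant

    @property
    def patient_score(self) -> float:
        return self.n_correct / self.n_images


def patient_score(predictions: PredictionSet | Sequence) -> PatientResult:
    """Score the predictions of a single patient.

    All predictions must share one true label (patients are single-class).
    The assigned patient label is the majority of predicted labels, ties
    falling to malignant like the image-level vote.
    """
    preds = list(predictions)
    if not preds:
        raise ValueError("patient must have at least one prediction")
    truths = {p.true_label for p in preds}
    if len(truths) != 1 or None in truths:
        raise ValueError(f"patient predictions carry mixed/missing true labels: {truths}")
    true_label = truths.pop()
    n = len(preds)
    n_correct = sum(p.predicted_label == p.true_label for p in preds)
    n_malig = sum(p.predicted_label == "malignant" for p in preds)
    n_benign = n - n_malig
    assigned = POSITIVE_CLASS if n_benign > n_malig else TIE_PREDICTION
    return PatientResult(
        patient_id="",
        true_label=true_label,
        n_images=n,
        n_correct=n_correct,
        assigned_label=assigned,
        fraction_malignant=n_malig / n,
    )


def patient_results(
    predictions: PredictionSet, patients: Sequence[str]
) -> list[PatientResult]:
    """Group a fold's predictions by patient and score each one."""
    if len(patients) != len(predictions):
        raise ValueError("one patient id per prediction required")
    groups: dict[str, list] = {}
    for p, pid in zip(predictions, patients):
        groups.setdefault(str(pid), []).append(p)
    out = []
    for pid in sorted(groups):
        r = patient_score(groups[pid])
        out.append(
            PatientResult(
                patient_id=pid,
                true_label=r.true_label,
                n_images=r.n_images,
                n_correct=r.n_correct,
                assigned_label=r.assigned_label,
                fraction_malignant=r.fraction_malignant,
            )
        )
    return out


def pla(results: Sequence[PatientResult] | Sequence[float]) -> float:
    """Patient-Level Accuracy: unweighted mean of patient scores."""
    if len(results) == 0:
        raise ValueError("PLA of an empty patient list is undefined")
    scores = [
        r.patient_score if isinstance(r, PatientResult) else float(r) for r in results
    ]
    return float(np.mean(scores))


def image_metrics(predictions: PredictionSet) -> dict[str, float | None]:
    """Image-level accuracy/precision/recall/F1/AUC with benign as positive.

    AUC is computed from the benign-neighbour-fraction score by rank
    statistic; with a single-class truth set it is undefined and reported as
    ``None`` with a warning.
    """
    preds = list(predictions)
    if not preds:
        raise ValueError("empty prediction set")
    y_true = [p.true_label for p in preds]
    if any(t is None for t in y_true):
        raise ValueError("image_metrics requires true labels")
    y_pred = [p.predicted_label for p in preds]
    scores = [p.score for p in preds]
    acc = float(np.mean([t == q for t, q in zip(y_true, y_pred)]))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, pos_label=POSITIVE_CLASS, average="binary",
        zero_division=0.0, labels=list(CLASS_ORDER),
    )
    if len(set(y_true)) < 2:
        warnings.warn("single-class truth set: AUC undefined", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score([t == POSITIVE_CLASS for t in y_true], scores))
    return {
        "image_accuracy": acc,
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "auc": auc,
    }


def confusion(predictions: PredictionSet) -> np.ndarray:
    """2x2 confusion matrix, rows = truth, cols = prediction, benign first."""
    y_true = [p.true_label for p in predictions]
    y_pred = [p.predicted_label for p in predictions]
    return _sk_confusion(y_true, y_pred, labels=list(CLASS_ORDER)).astype(float)


@dataclass
class FoldReport:
    """All evaluation artifacts of a single fold."""

    fold_index: int
    patient_results: list[PatientResult]
    pla: float
    confusion: np.ndarray
    metrics: dict[str, float | None]
    n_test_images: int

    @classmethod
    def from_predictions(
        cls, fold_index: int, predictions: PredictionSet, patients: Sequence[str]
    ) -> "FoldReport":
        presults = patient_results(predictions, patients)
        return cls(
            fold_index=fold_index,
            patient_results=presults,
            pla=pla(presults),
            confusion=confusion(predictions),
            metrics=image_metrics(predictions),
            n_test_images=len(predictions),
        )


@dataclass
class PatientFoldGrid:
    """Patient x fold view of test predictions.

    ``fraction`` holds, for each (patient, fold) cell, the fraction of that
    patient's test images labelled malignant (NaN when the patient is not in
    that fold's test set); ``assigned`` holds the majority-assigned label.
    Rows list benign patients first, then malignant, mirroring how a
    reviewer reads the grid for unstable patients (assigned label changing
    across folds).
    """

    fraction: pd.DataFrame
    assigned: pd.DataFrame
    true_labels: pd.Series

    def unstable_patients(self) -> list[str]:
        out = []
        for pid, row in self.assigned.iterrows():
            seen = set(row.dropna())
            if len(seen) > 1:
                out.append(pid)
        return out


@dataclass
class EvaluationReport:
    """Fold-averaged evaluation: mean +/- sd metrics, averaged confusion."""

    fold_reports: list[FoldReport]
    pla_mean: float
    pla_sd: float
    metrics_mean: dict[str, float | None]
    metrics_sd: dict[str, float | None]
    confusion_mean: np.ndarray
    grid: PatientFoldGrid

    @property
    def pla_per_fold(self) -> list[float]:
        return [f.pla for f in self.fold_reports]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name in METRIC_NAMES:
            if name == "pla":
                mean, sd = self.pla_mean, self.pla_sd
            else:
                mean, sd = self.metrics_mean.get(name), self.metrics_sd.get(name)
            rows.append({"metric": name, "mean": mean, "sd": sd})
        return pd.DataFrame(rows)

    def write(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.metrics_frame().to_csv(directory / f"{prefix}metrics.csv", index=False)
        pd.DataFrame(
            self.confusion_mean, index=list(CLASS_ORDER), columns=list(CLASS_ORDER)
        ).to_csv(directory / f"{prefix}confusion_mean.csv")
        self.grid.fraction.to_csv(directory / f"{prefix}patient_grid_fraction.csv")
        self.grid.assigned.to_csv(directory / f"{prefix}patient_grid_assigned.csv")


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def patient_fold_grid(fold_reports: Sequence[FoldReport]) -> PatientFoldGrid:
    """Assemble the patient x fold grid from per-fold patient results."""
    true_label: dict[str, str] = {}
    for fr in fold_reports:
        for r in fr.patient_results:
            prev = true_label.setdefault(r.patient_id, r.true_label)
            if prev != r.true_label:
                raise ValueError(f"patient {r.patient_id} has inconsistent true labels")
    benign = sorted(p for p, t in true_label.items() if t == "benign")
    malignant = sorted(p for p, t in true_label.items() if t == "malignant")
    index = benign + malignant
    cols = [fr.fold_index for fr in fold_reports]
    frac = pd.DataFrame(np.nan, index=index, columns=cols)
    assigned = pd.DataFrame(np.nan, index=index, columns=cols, dtype=object)
    for fr in fold_reports:
        for r in fr.patient_results:
            frac.loc[r.patient_id, fr.fold_index] = r.fraction_malignant
            assigned.loc[r.patient_id, fr.fold_index] = r.assigned_label
    return PatientFoldGrid(frac, assigned, pd.Series(true_label).reindex(index))


def fold_average(fold_reports: Sequence[FoldReport]) -> EvaluationReport:
    """Aggregate per-fold reports: element-wise confusion mean, metric mean/sd."""
    if len(fold_reports) == 0:
        raise ValueError("need at least one fold")
    keys = set(fold_reports[0].metrics)
    for fr in fold_reports[1:]:
        if set(fr.metrics) != keys:
            raise ValueError("folds report mismatched metric sets")
    pla_mean, pla_sd = _mean_sd([fr.pla for fr in fold_reports])
    metrics_mean: dict[str, float | None] = {}
    metrics_sd: dict[str, float | None] = {}
    for name in keys:
        vals = [fr.metrics[name] for fr in fold_reports]
        if any(v is None for v in vals):
            metrics_mean[name] = None
            metrics_sd[name] = None
        else:
            metrics_mean[name], metrics_sd[name] = _mean_sd(vals)  # type: ignore[arg-type]
    conf = np.mean([fr.confusion for fr in fold_reports], axis=0)
    return EvaluationReport(
        fold_reports=list(fold_reports),
        pla_mean=pla_mean,
        pla_sd=pla_sd,
        metrics_mean=metrics_mean,
        metrics_sd=metrics_sd,
        confusion_mean=conf,
        grid=patient_fold_grid(fold_reports),
    )
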