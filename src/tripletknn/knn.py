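"""k-nearest-neighbour classification over embeddings, with evidence.

The classifier is deliberately simple: a test embedding is labelled by
majority vote over its k nearest training embeddings. Each prediction keeps
its *neighbour evidence* — the ordered (train image id, distance, label)
triples — which is the basis of the pipeline's interpretability: a reviewer
can inspect exactly which training patches supported a call.

Policies are pinned down so results are deterministic and testable:

* vote ties (possible for even k) predict **malignant** — in the clinical
  framing, missing a malignancy is the costly error;
* equidistant neighbours at the k-th rank are resolved by stable training
  order (lowest row index first);
* the positive-class score is the fraction of benign neighbours, so under
  odd k "predicted benign" and "score > 0.5" coincide.

Distances are computed densely (corpora here are small, <= 1e4 rows); no
approximate indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances as _sk_pairwise

POSITIVE_CLASS = "benign"   # per the evaluation convention
TIE_PREDICTION = "malignant"


@dataclass(frozen=True)
class NeighborEvidence:
    """Ordered k-nearest training neighbours of one test image."""

    neighbor_ids: tuple[str, ...]
    distances: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.distances)
        if d.size and np.any(np.diff(d) < -1e-12):
            raise ValueError("neighbour distances must be nondecreasing")


@dataclass(frozen=True)
class Prediction:
    image_id: str
    true_label: str | None
    predicted_label: str
    score: float                    # fraction of benign neighbours
    evidence: NeighborEvidence


@dataclass
class PredictionSet:
    """Per-image predictions for one test fold."""

    predictions: list[Prediction]
    k: int
    distance: str

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    def __getitem__(self, image_id: str) -> Prediction:
        for p in self.predictions:
            if p.image_id == image_id:
                return p
        raise KeyError(f"no prediction for image {image_id!r}")

    @property
    def image_ids(self) -> list[str]:
        return [p.image_id for p in self.predictions]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.predictions:
            row: dict = {
                "image_id": p.image_id,
                "true_label": p.true_label if p.true_label is not None else "",
                "predicted_label": p.predicted_label,
                "score": p.score,
            }
            for j, (nid, nd) in enumerate(zip(p.evidence.neighbor_ids, p.evidence.distances)):
                row[f"neighbor{j + 1}_id"] = nid
                row[f"neighbor{j + 1}_distance"] = nd
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _stable_neighbor_order(dist_row: np.ndarray) -> np.ndarray:
    # lexsort: primary key distance, secondary key training row index
    return np.lexsort((np.arange(dist_row.size), dist_row))


def vote(labels: Sequence[str]) -> tuple[str, float]:
    """Majority vote with the documented tie policy; returns (label, score)."""
    n_pos = sum(1 for lb in labels if lb == POSITIVE_CLASS)
    score = n_pos / len(labels)
    # a strict benign majority predicts benign; ties fall to malignant
    label = POSITIVE_CLASS if 2 * n_pos > len(labels) else TIE_PREDICTION
    return label, score


def knn_predict(
    train_embeddings: np.ndarray,
    train_labels: Sequence[str],
    test_embeddings: np.ndarray,
    k: int = 3,
    distance: str = "euclidean",
    train_ids: Sequence[str] | None = None,
    test_ids: Sequence[str] | None = None,
    test_labels: Sequence[str] | None = None,
) -> PredictionSet:
    """Classify every test row by majority vote over its k nearest train rows.

    ``k`` larger than the training set is clamped with a warning; an empty
    test set yields an empty :class:`PredictionSet`.
    """
    Xtr = np.asarray(train_embeddings, dtype=np.float64)
    Xte = np.asarray(test_embeddings, dtype=np.float64)
    y = list(train_labels)
    if Xtr.shape[0] == 0:
        raise ValueError("training set must be nonempty")
    if Xtr.shape[0] != len(y):
        raise ValueError("train embeddings/labels length mismatch")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > Xtr.shape[0]:
        warnings.warn(
            f"k={k} exceeds training size {Xtr.shape[0]}; clamping", stacklevel=2
        )
        k = Xtr.shape[0]
    if train_ids is None:
        train_ids = [f"train{i}" for i in range(Xtr.shape[0])]
    if test_ids is None:
        test_ids = [f"test{i}" for i in range(Xte.shape[0])]
    if Xte.shape[0] == 0:
        return PredictionSet([], k, distance)
    D = _sk_pairwise(Xte, Xtr, metric=distance)
    preds = []
    for i in range(Xte.shape[0]):
        order = _stable_neighbor_order(D[i])[:k]
        nbr_labels = tuple(y[j] for j in order)
        label, score = vote(nbr_labels)
        preds.append(
            Prediction(
                image_id=str(test_ids[i]),
                true_label=None if test_labels is None else str(test_labels[i]),
                predicted_label=label,
                score=score,
                evidence=NeighborEvidence(
                    neighbor_ids=tuple(str(train_ids[j]) for j in order),
                    distances=tuple(float(D[i, j]) for j in order),
                    labels=nbr_labels,
                ),
            )
        )
    return PredictionSet(preds, k, distance)


def k_sweep(
    train_embeddings: np.ndarray,
    train_labels: Sequence[str],
    test_embeddings: np.ndarray,
    test_labels: Sequence[str],
    test_patients: Sequence[str],
    k_values: Sequence[int],
    distance: str = "euclidean",
) -> pd.DataFrame:
    """Image accuracy and patient-level accuracy as a function of k.

    Used to check the flatness of accuracy in k — on a well-separated
    corpus the choice of k barely matters.
    """
    from .evaluation import patient_results, pla  # local import avoids a cycle

    if len(k_values) == 0:
        raise ValueError("k_values must be nonempty")
    rows = []
    for k in k_values:
        pset = knn_predict(
            train_embeddings, train_labels, test_embeddings, k=k,
            distance=distance, test_labels=test_labels,
        )
        correct = [p.predicted_label == p.true_label for p in pset]
        acc = float(np.mean(correct))
        presults = patient_results(pset, test_patients)
        rows.append({"k": k, "image_accuracy": acc, "pla": pla(presults)})
    return pd.DataFrame(rows)
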