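import numpy as np
import pytest

from tripletknn.knn import NeighborEvidence, Prediction, PredictionSet
from tripletknn.synthetic import SyntheticSpec, generate_corpus, make_default_folds


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast, clearly separable corpus for plumbing tests."""
    return SyntheticSpec(
        n_patients_benign=4,
        n_patients_malignant=4,
        images_per_patient=4,
        feature_dim=16,
        class_separation=8.0,
        patient_spread=1.0,
        noise_sd=1.0,
        magnifications=(40, 100),
        magnification_shift=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec):
    return generate_corpus(tiny_spec)


@pytest.fixture(scope="session")
def tiny_folds(tiny_corpus):
    manifest, _ = tiny_corpus
    return make_default_folds(manifest, k=3, seed=7)


def make_prediction(image_id, true_label, predicted_label, score=None, k=3):
    """A minimal Prediction with consistent synthetic evidence."""
    if score is None:
        score = 1.0 if predicted_label == "benign" else 0.0
    n_b = round(score * k)
    labels = ("benign",) * n_b + ("malignant",) * (k - n_b)
    return Prediction(
        image_id=image_id,
        true_label=true_label,
        predicted_label=predicted_label,
        score=score,
        evidence=NeighborEvidence(
            tuple(f"t{i}" for i in range(k)),
            tuple(float(i) for i in range(k)),
            labels,
        ),
    )


def make_prediction_set(rows, k=3):
    """rows: iterable of (image_id, true_label, predicted_label[, score])."""
    preds = [make_prediction(*row, k=k) for row in rows]
    return PredictionSet(preds, k=k, distance="euclidean")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
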