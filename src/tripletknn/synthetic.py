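"""Synthetic feature-table corpora with histopathology-like structure.

Real patch corpora extracted through a frozen CNN show three kinds of
structure that the downstream pipeline relies on: (i) a class-level offset
between benign and malignant feature clouds, (ii) patient-level coherence —
images of one patient cluster around a patient-specific mean, with occasional
"straddler" patients whose images sit on both sides of the class boundary,
and (iii) a mild per-magnification shift. The generator emulates exactly
these with a hierarchical Gaussian model:

    class mean  →  patient mean  →  per-magnification offset  →  image noise

Distances are controlled directly: ``class_separation`` is the Euclidean
distance between the two class mean vectors, ``patient_spread`` the distance
of a patient mean from its class mean, ``magnification_shift`` the distance
of a (patient, magnification) mean from the patient mean, and ``noise_sd``
the per-coordinate standard deviation of the final image draw. Everything is
deterministic given ``seed``.

What this model does *not* emulate: stain variation, spatial texture, heavy
tails, class-conditional covariance structure, or the anisotropic geometry of
real CNN features. Results on it demonstrate pipeline correctness, not
clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (
    BENIGN_SUBCLASSES,
    MAGNIFICATIONS,
    MALIGNANT_SUBCLASSES,
    FoldSplit,
    ImageRecord,
    Manifest,
    validate_fold,
)

#: BreakHis patient counts per subclass (24 benign / 58 malignant patients)
#: and total image counts per subclass, used to shape realistic corpora.
BREAKHIS_PATIENTS = {
    "A": 4, "F": 10, "TA": 7, "PT": 3,
    "DC": 38, "LC": 5, "MC": 9, "PC": 6,
}
BREAKHIS_IMAGES = {
    "A": 444, "F": 1014, "TA": 453, "PT": 569,
    "DC": 3451, "LC": 626, "MC": 792, "PC": 560,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the hierarchical Gaussian corpus generator."""

    n_patients_benign: int = 10
    n_patients_malignant: int = 10
    images_per_patient: int = 8          # per magnification
    feature_dim: int = 2048
    class_separation: float = 3.0
    patient_spread: float = 2.0
    noise_sd: float = 1.0
    magnifications: tuple[int, ...] = MAGNIFICATIONS
    magnification_shift: float = 0.5
    n_straddlers: int = 0                # patients (per class) with mixed geometry
    straddle_fraction: float = 0.5       # fraction of a straddler's images drawn
                                         # around the opposite class mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients_benign < 1 or self.n_patients_malignant < 1:
            raise ValueError("need at least one patient per class")
        if self.images_per_patient < 1:
            raise ValueError("images_per_patient must be >= 1")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if self.class_separation < 0 or self.patient_spread < 0 or self.magnification_shift < 0:
            raise ValueError("separations and spreads must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.magnifications or any(m not in MAGNIFICATIONS for m in self.magnifications):
            raise ValueError(f"magnifications must be a nonempty subset of {MAGNIFICATIONS}")
        if not 0.0 <= self.straddle_fraction <= 1.0:
            raise ValueError("straddle_fraction must lie in [0, 1]")


def _unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    n = np.linalg.norm(v)
    while n == 0.0:  # pragma: no cover - measure-zero event
        v = rng.standard_normal(dim)
        n = np.linalg.norm(v)
    return v / n


def generate_corpus(spec: SyntheticSpec) -> tuple[Manifest, np.ndarray]:
    """Draw a manifest plus feature table from the hierarchical model.

    Record ids mimic the BreakHis token layout (``SYN_B_A-b00-40-001``);
    subclasses are assigned round-robin within each class; ``source`` is the
    row index into the returned ``(n_images, feature_dim)`` float array.
    """
    rng = np.random.default_rng(spec.seed)
    dim = spec.feature_dim
    axis = _unit(rng, dim)
    class_means = {
        "benign": +0.5 * spec.class_separation * axis,
        "malignant": -0.5 * spec.class_separation * axis,
    }
    per_class = {
        "benign": (spec.n_patients_benign, "B", BENIGN_SUBCLASSES, "b"),
        "malignant": (spec.n_patients_malignant, "M", MALIGNANT_SUBCLASSES, "m"),
    }
    records: list[ImageRecord] = []
    rows: list[np.ndarray] = []
    for cls in ("benign", "malignant"):
        n_pat, letter, subclasses, prefix = per_class[cls]
        other = "malignant" if cls == "benign" else "benign"
        for p in range(n_pat):
            patient_id = f"{prefix}{p:02d}"
            subclass = subclasses[p % len(subclasses)]
            pmean = class_means[cls] + spec.patient_spread * _unit(rng, dim)
            pmean_other = class_means[other] + spec.patient_spread * _unit(rng, dim)
            straddler = p < spec.n_straddlers
            for mag in spec.magnifications:
                mmean = pmean + spec.magnification_shift * _unit(rng, dim)
                mmean_other = pmean_other + spec.magnification_shift * _unit(rng, dim)
                for j in range(spec.images_per_patient):
                    crossed = straddler and rng.random() < spec.straddle_fraction
                    centre = mmean_other if crossed else mmean
                    rows.append(centre + spec.noise_sd * rng.standard_normal(dim))
                    records.append(
                        ImageRecord(
                            image_id=f"SYN_{letter}_{subclass}-{patient_id}-{mag}-{j:03d}",
                            patient_id=patient_id,
                            class_label=cls,
                            subclass=subclass,
                            magnification=mag,
                            source=len(rows) - 1,
                        )
                    )
    features = np.asarray(rows, dtype=np.float64)
    prov = f"synthetic corpus seed={spec.seed} spec={spec}"
    return Manifest(records, prov), features


def generate_breakhis_shaped_corpus(
    seed: int,
    scale: float = 1.0,
    feature_dim: int = 2048,
    class_separation: float = 3.0,
    patient_spread: float = 2.0,
    noise_sd: float = 1.0,
    magnification_shift: float = 0.5,
) -> tuple[Manifest, np.ndarray]:
    """A corpus whose patient and image counts follow the BreakHis census.

    At ``scale=1`` the manifest has 82 patients (24 benign, 58 malignant)
    split over the eight subclasses with per-subclass image totals
    proportional to the real corpus (7909 images over four magnifications).
    ``scale`` shrinks the patient counts proportionally, preserving the
    benign:malignant ratio within rounding; per-patient image counts keep the
    real per-patient rate so subclass image totals stay proportional too.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    n_pat = {s: round(n * scale) for s, n in BREAKHIS_PATIENTS.items()}
    if sum(n_pat[s] for s in BENIGN_SUBCLASSES) < 1 or sum(n_pat[s] for s in MALIGNANT_SUBCLASSES) < 1:
        raise ValueError(f"scale={scale} leaves no patients in one class")
    # images per patient per magnification at the real corpus' rate
    imgs_per_mag = {
        s: max(1, round(BREAKHIS_IMAGES[s] / BREAKHIS_PATIENTS[s] / len(MAGNIFICATIONS)))
        for s in BREAKHIS_PATIENTS
    }
    rng = np.random.default_rng(seed)
    axis = _unit(rng, feature_dim)
    class_means = {
        "benign": +0.5 * class_separation * axis,
        "malignant": -0.5 * class_separation * axis,
    }
    records: list[ImageRecord] = []
    rows: list[np.ndarray] = []
    counter = 0
    for cls, subclasses, letter, prefix in (
        ("benign", BENIGN_SUBCLASSES, "B", "b"),
        ("malignant", MALIGNANT_SUBCLASSES, "M", "m"),
    ):
        for subclass in subclasses:
            for p in range(n_pat[subclass]):
                patient_id = f"{prefix}{counter:03d}"
                counter += 1
                pmean = class_means[cls] + patient_spread * _unit(rng, feature_dim)
                for mag in MAGNIFICATIONS:
                    mmean = pmean + magnification_shift * _unit(rng, feature_dim)
                    for j in range(imgs_per_mag[subclass]):
                        rows.append(mmean + noise_sd * rng.standard_normal(feature_dim))
                        records.append(
                            ImageRecord(
                                image_id=f"SYN_{letter}_{subclass}-{patient_id}-{mag}-{j:03d}",
                                patient_id=patient_id,
                                class_label=cls,
                                subclass=subclass,
                                magnification=mag,
                                source=len(rows) - 1,
                            )
                        )
    features = np.asarray(rows, dtype=np.float64)
    prov = f"synthetic BreakHis-shaped corpus seed={seed} scale={scale}"
    return Manifest(records, prov), features


def make_default_folds(
    manifest: Manifest, k: int = 5, seed: int = 0, train_fraction: float = 0.7
) -> list[FoldSplit]:
    """Draw ``k`` independent patient-disjoint 70/30 splits, class-stratified.

    Mirrors the released BreakHis protocol: each fold is an independent
    random draw of ~70% of patients per class into training, the rest into
    test (the five folds are trials, not a partition). Every returned split
    passes :func:`tripletknn.records.validate_fold` by construction.
    """
    by_class: dict[str, list[str]] = {"benign": [], "malignant": []}
    for pid in sorted(manifest.patients):
        labels = {r.class_label for r in manifest.records if r.patient_id == pid}
        if len(labels) != 1:
            raise ValueError(f"patient {pid} has mixed true classes")
        by_class[labels.pop()].append(pid)
    for cls, pats in by_class.items():
        if len(pats) < 2:
            raise ValueError(f"need >=2 {cls} patients to split, got {len(pats)}")
    rng = np.random.default_rng(seed)
    folds = []
    for fold_index in range(1, k + 1):
        train_patients: set[str] = set()
        for pats in by_class.values():
            n_train = min(len(pats) - 1, max(1, round(train_fraction * len(pats))))
            chosen = rng.choice(len(pats), size=n_train, replace=False)
            train_patients.update(pats[i] for i in chosen)
        train_ids = frozenset(
            r.image_id for r in manifest.records if r.patient_id in train_patients
        )
        test_ids = frozenset(
            r.image_id for r in manifest.records if r.patient_id not in train_patients
        )
        split = FoldSplit(fold_index=fold_index, train_ids=train_ids, test_ids=test_ids)
        report = validate_fold(split, manifest)
        assert report.passed, f"internal error: generated invalid fold: {report}"
        folds.append(split)
    return folds


def write_features(path: str | Path, manifest: Manifest, features: np.ndarray) -> None:
    """Write a feature table as CSV: image_id column + f0..f{d-1} columns."""
    if len(manifest) != features.shape[0]:
        raise ValueError("manifest and feature table row counts differ")
    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    df.insert(0, "image_id", manifest.image_ids)
    # 17 significant digits make the float64 round-trip exact
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path, manifest: Manifest | None = None) -> np.ndarray:
    """Read a CSV feature table; if a manifest is given, rows are aligned to it."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "image_id" not in df.columns:
        raise ValueError(f"feature table {path} lacks an image_id column")
    df = df.set_index("image_id")
    if manifest is not None:
        missing = set(manifest.image_ids) - set(df.index)
        if missing:
            raise KeyError(f"feature table missing rows for {sorted(missing)[:5]}")
        df = df.loc[manifest.image_ids]
    return df.to_numpy(dtype=np.float64)


def features_for(
    manifest: Manifest, features: np.ndarray, image_ids: Sequence[str]
) -> np.ndarray:
    """Gather feature rows for the given image ids via their source indices."""
    idx = []
    for i in image_ids:
        src = manifest[i].source
        if not isinstance(src, (int, np.integer)):
            raise TypeError(f"record {i} has no feature-table source (source={src!r})")
        idx.append(int(src))
    return features[np.asarray(idx, dtype=int)]
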