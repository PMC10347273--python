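"""Interpretability artifacts: 2-D projections, patient views, explanations.

The embedding space is where the model's claims live (same-class images
close, different-class images apart); a 2-D projection of it is how a human
inspects those claims. The projector is always fitted on **training**
embeddings only and applied out-of-sample to test or foreign points, so the
picture cannot be flattered by the points being judged.

Three artifact families:

* projections — train/test/foreign point clouds with role tags, written as
  delimited text and optionally plotted;
* patient views — one patient's test points against the training background,
  with counts of points nearer the benign vs malignant training centroid
  (how "straddling" patients are spotted);
* explanation bundles — the k training neighbours behind one prediction,
  which *are* the prediction's justification under k-NN.

Out-of-distribution corpora have no formal score here: the artifact is the
projection itself plus a distance summary (fraction of foreign points whose
nearest training point is farther than the training set's own median
nearest-neighbour distance).

The canonical projector is UMAP with a fixed seed; a PCA projector satisfies
the identical contract, runs in milliseconds, and is the default where the
2-D view is only presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances as _sk_pairwise

from .knn import NeighborEvidence, PredictionSet

MIN_FIT_POINTS = 10


@dataclass
class Projector:
    """A fitted 2-D projector (train-only fit, out-of-sample transform)."""

    method: str
    seed: int
    input_dim: int
    _impl: object

    def transform(self, embeddings: np.ndarray) -> np.ndarray:
        X = np.asarray(embeddings, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(f"projector expects (n, {self.input_dim}) input, got {X.shape}")
        coords = np.asarray(self._impl.transform(X), dtype=np.float64)
        if not np.all(np.isfinite(coords)):
            raise FloatingPointError("projection produced non-finite coordinates")
        return coords


def fit_projection(
    train_embeddings: np.ndarray,
    method: str = "pca",
    seed: int = 0,
    **params,
) -> Projector:
    """Fit a reusable 2-D projector on training embeddings only."""
    X = np.asarray(train_embeddings, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("train embeddings must be 2-D")
    if X.shape[0] < MIN_FIT_POINTS:
        raise ValueError(f"need >= {MIN_FIT_POINTS} training points, got {X.shape[0]}")
    if method == "pca":
        impl = PCA(n_components=2, random_state=seed, **params).fit(X)
    elif method == "umap":
        import umap  # deferred: heavy numba JIT on import/first fit

        impl = umap.UMAP(n_components=2, random_state=seed, **params).fit(X)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return Projector(method=method, seed=seed, input_dim=X.shape[1], _impl=impl)


@dataclass
class ProjectionResult:
    """2-D coordinates plus identity/role metadata for a set of images."""

    frame: pd.DataFrame           # image_id, x, y, role, label, patient_id
    method: str
    seed: int

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy()

    def subset(self, role: str | None = None, patient_id: str | None = None) -> pd.DataFrame:
        df = self.frame
        if role is not None:
            df = df[df["role"] == role]
        if patient_id is not None:
            df = df[df["patient_id"] == patient_id]
        return df

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ProjectionResult":
        return cls(pd.read_csv(path, keep_default_na=False), method="", seed=-1)


def project(
    projector: Projector,
    embeddings: np.ndarray,
    role: str,
    image_ids: Sequence[str],
    labels: Sequence[str] | None = None,
    patients: Sequence[str] | None = None,
) -> ProjectionResult:
    """Transform embeddings out-of-sample, tagging every point with a role."""
    if role not in ("train", "test", "foreign"):
        raise ValueError("role must be train, test or foreign")
    coords = projector.transform(embeddings)
    n = coords.shape[0]
    if len(image_ids) != n:
        raise ValueError("one image_id per embedding row required")
    frame = pd.DataFrame(
        {
            "image_id": list(image_ids),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "role": role,
            "label": list(labels) if labels is not None else [""] * n,
            "patient_id": list(patients) if patients is not None else [""] * n,
        }
    )
    return ProjectionResult(frame, projector.method, projector.seed)


def combine(*results: ProjectionResult) -> ProjectionResult:
    frames = [r.frame for r in results]
    return ProjectionResult(
        pd.concat(frames, ignore_index=True), results[0].method, results[0].seed
    )


@dataclass
class PatientView:
    """One patient's projected points in the context of the training cloud."""

    patient_id: str
    points: pd.DataFrame
    background: pd.DataFrame
    n_near_benign: int
    n_near_malignant: int

    @property
    def straddles(self) -> bool:
        return self.n_near_benign > 0 and self.n_near_malignant > 0


def patient_view(projection: ProjectionResult, patient_id: str) -> PatientView:
    """Highlight a patient against the training background.

    Each of the patient's points is attributed to the nearer of the two
    class centroids of the projected *training* points; a patient with
    points on both sides is a straddler (the clinically unstable case).
    """
    pts = projection.frame[projection.frame["patient_id"] == patient_id]
    if pts.empty:
        raise KeyError(f"unknown patient {patient_id!r} in projection")
    train = projection.frame[projection.frame["role"] == "train"]
    if train.empty:
        raise ValueError("projection has no training background")
    centroids = {}
    for cls in ("benign", "malignant"):
        sel = train[train["label"] == cls]
        if sel.empty:
            raise ValueError(f"training background has no {cls} points")
        centroids[cls] = sel[["x", "y"]].to_numpy().mean(axis=0)
    xy = pts[["x", "y"]].to_numpy()
    d_b = np.linalg.norm(xy - centroids["benign"], axis=1)
    d_m = np.linalg.norm(xy - centroids["malignant"], axis=1)
    near_b = int(np.sum(d_b < d_m))
    return PatientView(
        patient_id=patient_id,
        points=pts.reset_index(drop=True),
        background=train.reset_index(drop=True),
        n_near_benign=near_b,
        n_near_malignant=len(pts) - near_b,
    )


@dataclass(frozen=True)
class ExplanationBundle:
    """The neighbour evidence behind one prediction, ready to render."""

    image_id: str
    predicted_label: str
    neighbor_ids: tuple[str, ...]
    distances: tuple[float, ...]
    labels: tuple[str, ...]
    thumbnail_paths: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": self.image_id,
                "predicted_label": self.predicted_label,
                "rank": j + 1,
                "neighbor_id": nid,
                "distance": d,
                "neighbor_label": lb,
                "thumbnail": self.thumbnail_paths[j] if self.thumbnail_paths else "",
            }
            for j, (nid, d, lb) in enumerate(
                zip(self.neighbor_ids, self.distances, self.labels)
            )
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ExplanationBundle":
        df = pd.read_csv(path, keep_default_na=False).sort_values("rank")
        return cls(
            image_id=str(df["image_id"].iloc[0]),
            predicted_label=str(df["predicted_label"].iloc[0]),
            neighbor_ids=tuple(df["neighbor_id"].astype(str)),
            distances=tuple(df["distance"].astype(float)),
            labels=tuple(df["neighbor_label"].astype(str)),
            thumbnail_paths=tuple(df["thumbnail"].astype(str))
            if df["thumbnail"].astype(str).str.len().any()
            else (),
        )


def explain_prediction(
    predictions: PredictionSet,
    image_id: str,
    thumbnails: dict[str, str] | None = None,
) -> ExplanationBundle:
    """Bundle the neighbours that produced one prediction."""
    p = predictions[image_id]
    ev: NeighborEvidence = p.evidence
    thumbs = ()
    if thumbnails is not None:
        thumbs = tuple(thumbnails.get(nid, "") for nid in ev.neighbor_ids)
    return ExplanationBundle(
        image_id=image_id,
        predicted_label=p.predicted_label,
        neighbor_ids=ev.neighbor_ids,
        distances=ev.distances,
        labels=ev.labels,
        thumbnail_paths=thumbs,
    )


def foreign_separation(train_xy: np.ndarray, foreign_xy: np.ndarray) -> float:
    """Fraction of foreign points projected clear of the training cloud.

    A foreign point counts as separated when its distance to the nearest
    training point exceeds the training set's median nearest-neighbour
    distance. Near 1.0 means the foreign corpus lands visibly outside the
    regions the classifier knows about.
    """
    train_xy = np.asarray(train_xy, dtype=float)
    foreign_xy = np.asarray(foreign_xy, dtype=float)
    if train_xy.shape[0] < 2 or foreign_xy.shape[0] < 1:
        raise ValueError("need >= 2 train points and >= 1 foreign point")
    Dtt = _sk_pairwise(train_xy)
    np.fill_diagonal(Dtt, np.inf)
    median_nn = float(np.median(Dtt.min(axis=1)))
    Dft = _sk_pairwise(foreign_xy, train_xy)
    return float(np.mean(Dft.min(axis=1) > median_nn))


def plot_projection(
    projection: ProjectionResult, path: str | Path, title: str = ""
) -> None:
    """Scatter the projection to a figure file (roles as markers, classes as colours)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    markers = {"train": "o", "test": "^", "foreign": "x"}
    colors = {"benign": "tab:blue", "malignant": "tab:red", "": "tab:gray"}
    for role, grp in projection.frame.groupby("role"):
        for label, sub in grp.groupby("label"):
            ax.scatter(
                sub["x"], sub["y"], s=12, alpha=0.7,
                marker=markers.get(str(role), "o"),
                c=colors.get(str(label), "tab:gray"),
                label=f"{role}/{label}" if label else str(role),
            )
    ax.legend(fontsize=8)
    ax.set_title(title or f"2-D projection ({projection.method})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
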