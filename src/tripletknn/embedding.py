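"""Trainable linear metric embedding with triplet margin loss.

The model is a single bias-free linear map W from backbone-feature space
(input_dim, 2048 in the reference setup) to a lower-dimensional embedding
space (embedding_dim, 512 by default): r = W x. Training pulls same-class
embeddings together and pushes different-class embeddings apart via the
triplet margin loss

    l(a, p, n) = max(0, d(r_a, r_p) - d(r_a, r_n) + m)

where a is the anchor, p a positive (same class), n a negative (other
class), d the model's distance (euclidean or cosine) and m > 0 the margin.

Triplets are mined online inside each mini-batch with the *semi-hard* rule:
a negative n qualifies for the pair (a, p) iff

    d(r_a, r_p) < d(r_a, r_n) < d(r_a, r_p) + m

i.e. the negative is already farther than the positive but still within the
margin. A direct consequence is that every mined triplet's loss lies
strictly inside (0, m). Among qualifying negatives the one closest to the
anchor is selected (deterministic; ties broken by lowest batch index), and
every (anchor, positive) ordered pair is considered.

The optimizer is Adam with L2 weight decay, implemented here directly; the
training loop is plain SGD over shuffled mini-batches and is bit-reproducible
for a fixed config seed. Gradients are exact: the hinge subgradient through
the chosen distance and, when embeddings are L2-normalized, through the
normalization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12
DISTANCES = ("euclidean", "cosine")


@dataclass(frozen=True)
class Triplet:
    """Row indices of (anchor, positive, negative) within one batch."""

    anchor: int
    positive: int
    negative: int


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    miner: str = "semi_hard"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0, weight_decay >= 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.miner not in ("semi_hard", "all_valid"):
            raise ValueError(f"unknown miner {self.miner!r}")


@dataclass
class EmbeddingModel:
    """The linear map plus the metric it was trained under."""

    weight: np.ndarray          # (embedding_dim, input_dim)
    distance: str = "euclidean"
    margin: float = 0.2
    normalized: bool = False

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if self.weight.ndim != 2:
            raise ValueError("weight must be a 2-D matrix")
        if self.distance not in DISTANCES:
            raise ValueError(f"distance must be one of {DISTANCES}")
        if self.margin <= 0:
            raise ValueError("margin must be positive")

    @property
    def input_dim(self) -> int:
        return self.weight.shape[1]

    @property
    def embedding_dim(self) -> int:
        return self.weight.shape[0]

    def copy(self) -> "EmbeddingModel":
        return EmbeddingModel(self.weight.copy(), self.distance, self.margin, self.normalized)

    def save(self, path: str | Path) -> None:
        header = json.dumps(
            {
                "format": "tripletknn-embedding",
                "version": 1,
                "distance": self.distance,
                "margin": self.margin,
                "normalized": self.normalized,
            }
        )
        np.savez(path, header=np.array(header), weight=self.weight)

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            if header.get("format") != "tripletknn-embedding":
                raise ValueError(f"{path} is not an embedding model file")
            return cls(
                weight=data["weight"],
                distance=header["distance"],
                margin=float(header["margin"]),
                normalized=bool(header["normalized"]),
            )


def init_model(
    input_dim: int,
    embedding_dim: int = 512,
    seed: int = 0,
    distance: str = "euclidean",
    margin: float = 0.2,
    normalized: bool = False,
) -> EmbeddingModel:
    """Random near-orthogonal initialization (rows of a QR-orthonormal frame).

    An orthonormal W preserves the geometry of the projected subspace, so the
    untrained model behaves like a random isometric projection rather than an
    arbitrary distortion.
    """
    if embedding_dim > input_dim:
        raise ValueError("embedding_dim must not exceed input_dim")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((input_dim, embedding_dim))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix sign convention for determinism
    return EmbeddingModel(q.T.copy(), distance, margin, normalized)


def calibrate_init_scale(
    model: EmbeddingModel,
    features: np.ndarray,
    target: float | None = None,
    n_sample: int = 256,
) -> EmbeddingModel:
    """Rescale an initial W so embedding distances are commensurate with the margin.

    The triplet hinge only produces gradients where the semi-hard band
    (d_ap, d_ap + m) is populated; if typical embedding distances dwarf the
    margin, that band is a sliver and training stalls. Rescaling the
    initialization so the *median* pairwise embedding distance equals
    ``target`` (default 2 m) puts the untrained model in the loss's sensitive
    regime. Deterministic (uses an evenly spaced row subsample); a no-op for
    cosine distance and normalized embeddings, both scale-invariant.
    """
    if model.distance == "cosine" or model.normalized:
        return model
    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] < 2:
        return model
    idx = np.unique(np.linspace(0, X.shape[0] - 1, min(n_sample, X.shape[0])).astype(int))
    E = X[idx] @ model.weight.T
    iu = np.triu_indices(E.shape[0], 1)
    d0 = float(np.median(pairwise_distances(E, "euclidean")[iu]))
    if d0 <= 0:
        return model
    tgt = 2.0 * model.margin if target is None else float(target)
    out = model.copy()
    out.weight *= tgt / d0
    return out


def identity_model(
    dim: int, distance: str = "euclidean", margin: float = 0.2
) -> EmbeddingModel:
    """The no-op embedding used by the ablation path (raw features through)."""
    return EmbeddingModel(np.eye(dim), distance, margin, normalized=False)


def embed(model: EmbeddingModel, features: np.ndarray) -> np.ndarray:
    """Apply the linear map row-wise; optional L2 normalization."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"features must be (n, {model.input_dim}), got {X.shape}"
        )
    Y = X @ model.weight.T
    if model.normalized:
        norms = np.maximum(np.linalg.norm(Y, axis=1, keepdims=True), _EPS)
        Y = Y / norms
    return Y


def triplet_loss(d_ap: float, d_an: float, m: float) -> float:
    """Hinge of the margin violation: max(0, d_ap - d_an + m)."""
    if d_ap < 0 or d_an < 0:
        raise ValueError("distances must be nonnegative")
    if m <= 0:
        raise ValueError("margin must be positive")
    if not (np.isfinite(d_ap) and np.isfinite(d_an)):
        raise ValueError("distances must be finite")
    return max(0.0, d_ap - d_an + m)


def pairwise_distances(X: np.ndarray, distance: str) -> np.ndarray:
    """Dense pairwise distance matrix under the model metric."""
    X = np.asarray(X, dtype=np.float64)
    if distance == "euclidean":
        sq = np.sum(X * X, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        return np.sqrt(np.maximum(d2, 0.0))
    if distance == "cosine":
        norms = np.maximum(np.linalg.norm(X, axis=1), _EPS)
        sim = (X @ X.T) / np.outer(norms, norms)
        return 1.0 - np.clip(sim, -1.0, 1.0)
    raise ValueError(f"distance must be one of {DISTANCES}")


def mine_semi_hard(
    embeddings: np.ndarray,
    labels: Sequence,
    m: float,
    distance: str = "euclidean",
) -> list[Triplet]:
    """Select semi-hard triplets within a batch.

    For every ordered same-label pair (a, p), a != p, the negatives with
    d(a, p) < d(a, n) < d(a, p) + m are candidates; the closest one to the
    anchor is chosen (lowest index on exact ties). Returns an empty list —
    with a logged warning — when the batch holds a single class, and an empty
    list silently when no triplet qualifies.
    """
    if m <= 0:
        raise ValueError("margin must be positive")
    y = np.asarray(labels)
    n = len(y)
    if np.asarray(embeddings).shape[0] != n:
        raise ValueError("embeddings and labels length mismatch")
    if len(np.unique(y)) < 2:
        logger.warning("mine_semi_hard: single-class batch, no triplets minable")
        return []
    D = pairwise_distances(embeddings, distance)
    same = y[:, None] == y[None, :]
    triplets: list[Triplet] = []
    for a in range(n):
        pos_idx = np.nonzero(same[a])[0]
        neg_idx = np.nonzero(~same[a])[0]
        if neg_idx.size == 0:
            continue
        d_neg = D[a, neg_idx]
        for p in pos_idx:
            if p == a:
                continue
            d_ap = D[a, p]
            ok = (d_neg > d_ap) & (d_neg < d_ap + m)
            if not ok.any():
                continue
            cand = neg_idx[ok]
            best = cand[np.argmin(d_neg[ok])]  # argmin is stable: lowest index on ties
            triplets.append(Triplet(a, int(p), int(best)))
    return triplets


def mine_all_valid(
    embeddings: np.ndarray, labels: Sequence, m: float, distance: str = "euclidean"
) -> list[Triplet]:
    """Every label-valid (a, p, n) triplet with an active hinge (loss > 0)."""
    y = np.asarray(labels)
    n = len(y)
    if len(np.unique(y)) < 2:
        logger.warning("mine_all_valid: single-class batch, no triplets minable")
        return []
    D = pairwise_distances(embeddings, distance)
    same = y[:, None] == y[None, :]
    out = []
    for a in range(n):
        for p in np.nonzero(same[a])[0]:
            if p == a:
                continue
            for neg in np.nonzero(~same[a])[0]:
                if D[a, p] - D[a, neg] + m > 0:
                    out.append(Triplet(a, int(p), int(neg)))
    return out


@dataclass(frozen=True)
class EpochStats:
    """Per-epoch summary of the mined-triplet losses."""

    epoch: int
    mean_loss: float
    min_loss: float
    max_loss: float
    n_triplets: int


def _distance_grads(
    R: np.ndarray, i: np.ndarray, j: np.ndarray, distance: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """d(R_i, R_j) with gradients w.r.t. R_i and R_j, vectorized over pairs."""
    a, b = R[i], R[j]
    if distance == "euclidean":
        diff = a - b
        d = np.linalg.norm(diff, axis=1)
        g = diff / np.maximum(d, _EPS)[:, None]
        return d, g, -g
    # cosine: d = 1 - a.b / (|a||b|)
    na = np.maximum(np.linalg.norm(a, axis=1), _EPS)
    nb = np.maximum(np.linalg.norm(b, axis=1), _EPS)
    dot = np.sum(a * b, axis=1)
    d = 1.0 - dot / (na * nb)
    ga = -(b / (na * nb)[:, None] - (dot / (na**3 * nb))[:, None] * a)
    gb = -(a / (na * nb)[:, None] - (dot / (na * nb**3))[:, None] * b)
    return d, ga, gb


def _batch_gradient(
    model: EmbeddingModel, Xb: np.ndarray, triplets: list[Triplet]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean triplet loss over the batch and its gradient w.r.t. W."""
    Y = Xb @ model.weight.T
    if model.normalized:
        norms = np.maximum(np.linalg.norm(Y, axis=1, keepdims=True), _EPS)
        R = Y / norms
    else:
        R = Y
    ai = np.array([t.anchor for t in triplets])
    pi = np.array([t.positive for t in triplets])
    ni = np.array([t.negative for t in triplets])
    d_ap, g_ap_a, g_ap_p = _distance_grads(R, ai, pi, model.distance)
    d_an, g_an_a, g_an_n = _distance_grads(R, ai, ni, model.distance)
    losses = d_ap - d_an + model.margin
    active = losses > 0
    loss = float(np.mean(np.maximum(losses, 0.0)))
    gR = np.zeros_like(R)
    if active.any():
        w = active.astype(np.float64) / len(triplets)
        np.add.at(gR, ai, w[:, None] * (g_ap_a - g_an_a))
        np.add.at(gR, pi, w[:, None] * g_ap_p)
        np.add.at(gR, ni, -w[:, None] * g_an_n)
    if model.normalized:
        # back through r = y/|y|: g_y = (g_r - (g_r . r) r) / |y|
        norms = np.maximum(np.linalg.norm(Y, axis=1, keepdims=True), _EPS)
        gY = (gR - np.sum(gR * R, axis=1, keepdims=True) * R) / norms
    else:
        gY = gR
    gW = gY.T @ Xb
    return loss, gW


class _Adam:
    """Plain Adam with additive L2 weight decay."""

    def __init__(self, shape, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, W: np.ndarray, grad: np.ndarray) -> np.ndarray:
        g = grad + self.wd * W
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return W - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_embedding(
    features: np.ndarray,
    labels: Sequence,
    cfg: TrainConfig,
    model: EmbeddingModel,
) -> tuple[EmbeddingModel, list[EpochStats]]:
    """Fit the linear embedding by online triplet mining over mini-batches.

    Each step embeds the current batch, mines triplets with the configured
    strategy against those *current* embeddings, and takes one Adam step on
    the mean triplet loss. Per-epoch statistics aggregate the losses of all
    triplets at mining time; with the semi-hard miner these lie strictly
    inside (0, m) by construction, which is asserted.

    Deterministic for fixed ``cfg.seed`` and inputs. ``cfg.epochs == 0``
    returns an untouched copy of the initialization.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("features must be 2-D with one label per row")
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match model input_dim {model.input_dim}"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    mine = mine_semi_hard if cfg.miner == "semi_hard" else mine_all_valid
    model = model.copy()
    opt = _Adam(model.weight.shape, cfg.learning_rate, cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history: list[EpochStats] = []
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses: list[np.ndarray] = []
        epoch_count = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            R = embed(model, Xb)
            triplets = mine(R, yb, model.margin, model.distance)
            if not triplets:
                continue
            Dm = pairwise_distances(R, model.distance)
            step_losses = np.array(
                [Dm[t.anchor, t.positive] - Dm[t.anchor, t.negative] + model.margin
                 for t in triplets]
            )
            if cfg.miner == "semi_hard":
                assert np.all(step_losses > 0) and np.all(step_losses < model.margin + 1e-9), (
                    "semi-hard mined losses must lie in (0, m)"
                )
            loss, gW = _batch_gradient(model, Xb, triplets)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
            model.weight = opt.step(model.weight, gW)
            epoch_losses.append(step_losses)
            epoch_count += len(triplets)
        if epoch_count:
            all_losses = np.concatenate(epoch_losses)
            stats = EpochStats(
                epoch + 1,
                float(all_losses.mean()),
                float(all_losses.min()),
                float(all_losses.max()),
                epoch_count,
            )
        else:
            # the miner running dry usually means every triplet is easy now
            logger.info("epoch %d: no triplets mined", epoch + 1)
            stats = EpochStats(epoch + 1, 0.0, 0.0, 0.0, 0)
        history.append(stats)
    if history and all(h.n_triplets == 0 for h in history):
        warnings.warn("no triplets mined in any epoch; model unchanged in effect",
                      stacklevel=2)
    return model, history


def class_distance_ratio(
    embeddings: np.ndarray, labels: Sequence, distance: str = "euclidean"
) -> float:
    """Mean inter-class distance over mean intra-class distance.

    The quantity metric learning is meant to increase: > 1 means same-class
    points sit closer together than different-class points on average.
    """
    y = np.asarray(labels)
    D = pairwise_distances(embeddings, distance)
    same = (y[:, None] == y[None, :]) & ~np.eye(len(y), dtype=bool)
    diff = y[:, None] != y[None, :]
    if not same.any() or not diff.any():
        raise ValueError("need both intra- and inter-class pairs")
    return float(D[diff].mean() / D[same].mean())
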