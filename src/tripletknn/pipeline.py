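"""End-to-end runs: magnification-independent, magnification-specific, ablation.

A *run* executes, for each patient-disjoint fold: train the metric embedding
on the fold's training features -> embed train and test -> k-NN classify ->
evaluate at image and patient level; then fold-averages the five reports.

Three regimes:

* **MIB** (magnification-independent binary): one model over all images
  regardless of magnification.
* **MSB** (magnification-specific binary): four independent models, one per
  magnification, on magnification-restricted folds.
* **ablation**: the identical pipeline with the embedding layer removed —
  k-NN operates directly on the raw backbone features. Comparing a main run
  against its ablation isolates the contribution of metric learning.

Every run can write a self-describing directory: per-fold predictions,
models (main runs only), metric/confusion/patient-grid tables and a
metadata file carrying the full configuration and seeds, so any stage can be
re-run from its predecessors' files and a fixed-seed rerun reproduces the
report bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .embedding import (
    EmbeddingModel,
    TrainConfig,
    calibrate_init_scale,
    embed,
    init_model,
    train_embedding,
)
from .evaluation import EvaluationReport, FoldReport, fold_average
from .knn import PredictionSet, knn_predict
from .records import (
    MAGNIFICATIONS,
    FoldSplit,
    Manifest,
    restrict_fold,
    restrict_to_magnification,
    validate_fold,
)
from .synthetic import features_for

logger = logging.getLogger(__name__)

#: per-magnification k used by the magnification-specific ablation runs
ABLATION_MSB_K = {40: 3, 100: 7, 200: 5, 400: 9}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    mode: str = "MIB"               # MIB | MSB | ablation_MIB | ablation_MSB
    embedding_dim: int = 512
    distance: str = "euclidean"
    margin: float = 0.2
    normalized: bool = False
    train: TrainConfig = field(default_factory=TrainConfig)
    k: int = 3
    k_per_magnification: dict[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("MIB", "MSB", "ablation_MIB", "ablation_MSB"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def is_ablation(self) -> bool:
        return self.mode.startswith("ablation")

    def k_for(self, magnification: int | None) -> int:
        if magnification is not None and self.k_per_magnification:
            return self.k_per_magnification[magnification]
        return self.k

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _fold_seed(base: int, fold_index: int) -> int:
    # distinct, stable, below 2**31
    return (base * 100003 + fold_index) % (2**31 - 1)


def run_fold(
    manifest: Manifest,
    features: np.ndarray,
    split: FoldSplit,
    cfg: RunConfig,
    magnification: int | None = None,
) -> tuple[FoldReport, PredictionSet, EmbeddingModel | None]:
    """Execute one fold of the pipeline; stage failures name fold and stage."""
    stage = "validate"
    try:
        report = validate_fold(split, manifest)
        if not report.passed:
            raise ValueError(f"fold failed validation: {report}")
        train_ids = sorted(split.train_ids)
        test_ids = sorted(split.test_ids)
        Xtr = features_for(manifest, features, train_ids)
        Xte = features_for(manifest, features, test_ids)
        ytr = manifest.labels(train_ids)
        yte = manifest.labels(test_ids)

        model: EmbeddingModel | None
        if cfg.is_ablation:
            stage = "embed"
            model = None
            Etr, Ete = Xtr, Xte
        else:
            stage = "train_embedding"
            model0 = init_model(
                input_dim=Xtr.shape[1],
                embedding_dim=cfg.embedding_dim,
                seed=_fold_seed(cfg.seed, split.fold_index),
                distance=cfg.distance,
                margin=cfg.margin,
                normalized=cfg.normalized,
            )
            model0 = calibrate_init_scale(model0, Xtr)
            train_cfg = dataclasses.replace(
                cfg.train, seed=_fold_seed(cfg.train.seed, split.fold_index)
            )
            model, _history = train_embedding(Xtr, ytr, train_cfg, model0)
            stage = "embed"
            Etr = embed(model, Xtr)
            Ete = embed(model, Xte)

        stage = "knn"
        pset = knn_predict(
            Etr, ytr, Ete,
            k=cfg.k_for(magnification),
            distance=cfg.distance,
            train_ids=train_ids,
            test_ids=test_ids,
            test_labels=yte,
        )
        stage = "evaluate"
        frep = FoldReport.from_predictions(
            split.fold_index, pset, manifest.patient_of(test_ids)
        )
        return frep, pset, model
    except Exception as exc:
        raise RuntimeError(
            f"fold {split.fold_index}, stage {stage!r}: {exc}"
        ) from exc


def _write_run(
    outdir: Path,
    cfg: RunConfig,
    report: EvaluationReport,
    psets: dict[int, PredictionSet],
    models: dict[int, EmbeddingModel],
    prefix: str = "",
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.write(outdir, prefix=prefix)
    for i, pset in psets.items():
        pset.write(outdir / f"{prefix}predictions_fold{i}.csv")
    for i, model in models.items():
        model.save(outdir / f"{prefix}model_fold{i}.npz")
    meta = {
        "package": "tripletknn",
        "version": __version__,
        "numpy": np.__version__,
        "config": cfg.to_json(),
    }
    (outdir / f"{prefix}metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def run_mib(
    manifest: Manifest,
    features: np.ndarray,
    folds: Sequence[FoldSplit],
    cfg: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> EvaluationReport:
    """Magnification-independent run over all folds (main or ablation)."""
    cfg = cfg or RunConfig(mode="MIB")
    psets: dict[int, PredictionSet] = {}
    models: dict[int, EmbeddingModel] = {}
    fold_reports = []
    for split in folds:
        frep, pset, model = run_fold(manifest, features, split, cfg)
        fold_reports.append(frep)
        psets[split.fold_index] = pset
        if model is not None:
            models[split.fold_index] = model
    report = fold_average(fold_reports)
    if outdir is not None:
        _write_run(Path(outdir), cfg, report, psets, models)
    return report


def run_msb(
    manifest: Manifest,
    features: np.ndarray,
    folds: Sequence[FoldSplit],
    cfg: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict[int, EvaluationReport]:
    """Magnification-specific runs: one independent pipeline per magnification.

    Folds may come in globally (MIB scope) and are restricted per
    magnification, or already magnification-scoped. Magnifications with no
    test patients are skipped with a warning.
    """
    cfg = cfg or RunConfig(mode="MSB")
    present = sorted({r.magnification for r in manifest.records})
    reports: dict[int, EvaluationReport] = {}
    for mag in MAGNIFICATIONS:
        if mag not in present:
            warnings.warn(f"magnification {mag}x absent from manifest; skipped", stacklevel=2)
            continue
        sub_manifest = restrict_to_magnification(manifest, mag)
        fold_reports = []
        psets: dict[int, PredictionSet] = {}
        models: dict[int, EmbeddingModel] = {}
        usable = True
        for split in folds:
            scoped = split if split.scope == mag else restrict_fold(split, manifest, mag)
            if not scoped.train_ids or not scoped.test_ids:
                warnings.warn(
                    f"magnification {mag}x: fold {split.fold_index} has an empty side; skipped",
                    stacklevel=2,
                )
                usable = False
                break
            frep, pset, model = run_fold(sub_manifest, features, scoped, cfg, magnification=mag)
            fold_reports.append(frep)
            psets[split.fold_index] = pset
            if model is not None:
                models[split.fold_index] = model
        if not usable or not fold_reports:
            continue
        report = fold_average(fold_reports)
        reports[mag] = report
        if outdir is not None:
            _write_run(Path(outdir), cfg, report, psets, models, prefix=f"mag{mag}_")
    return reports


def run_ablation(
    manifest: Manifest,
    features: np.ndarray,
    folds: Sequence[FoldSplit],
    cfg: RunConfig | None = None,
    outdir: str | Path | None = None,
    msb: bool = False,
) -> EvaluationReport | dict[int, EvaluationReport]:
    """The pipeline without the embedding layer (k-NN on raw features).

    MSB ablation uses the per-magnification k map (3/7/5/9 for
    40/100/200/400x) unless the config overrides it. No model files are
    written — there is nothing trained to save.
    """
    if cfg is None:
        cfg = RunConfig(
            mode="ablation_MSB" if msb else "ablation_MIB",
            k_per_magnification=dict(ABLATION_MSB_K) if msb else None,
        )
    if not cfg.is_ablation:
        raise ValueError("run_ablation requires an ablation_* mode config")
    if cfg.mode == "ablation_MSB":
        if cfg.k_per_magnification is None:
            cfg = dataclasses.replace(cfg, k_per_magnification=dict(ABLATION_MSB_K))
        return run_msb(manifest, features, folds, cfg, outdir)
    return run_mib(manifest, features, folds, cfg, outdir)


def msb_summary(reports: dict[int, EvaluationReport]):
    """One row per metric, one column per magnification (mean +/- sd strings)."""
    import pandas as pd

    cols = {}
    for mag, rep in sorted(reports.items()):
        frame = rep.metrics_frame().set_index("metric")
        cols[f"{mag}x"] = {
            name: f"{row['mean'] * 100:.2f}±{row['sd'] * 100:.2f}"
            for name, row in frame.iterrows()
            if row["mean"] is not None and not np.isnan(row["mean"])
        }
    return pd.DataFrame(cols)
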