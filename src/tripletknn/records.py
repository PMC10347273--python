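"""Image records, manifests and patient-disjoint fold splits.

The data model mirrors the BreakHis breast-cancer histopathology corpus:
patches carry a binary class (benign/malignant), one of eight tumour
subclasses, a patient (slide) identifier and one of four optical
magnifications. Everything downstream — embedding training, k-NN
classification, patient-level scoring — is keyed on these fields, and the
train/test discipline is *patient-disjoint*: images of one patient never
appear on both sides of a fold.

Filename grammar
----------------
BreakHis filenames encode all metadata, e.g. ``SOB_B_TA-14-4659-40-001.png``:

    <procedure>_<B|M>_<subclass>-<year>-<slide id>-<magnification>-<seq>.png

``patient_id`` is the compound ``<year>-<slide id>`` token — the only patient
surrogate present in filenames. Subclass letters map onto the binary class:
A/F/TA/PT are benign (adenosis, fibroadenoma, tubular adenoma, phyllodes
tumour); DC/LC/MC/PC are malignant (ductal, lobular, mucinous and papillary
carcinoma).

Manifests are plain delimited text (CSV, header row) so that non-BreakHis
corpora and synthetic feature tables flow through the same downstream code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

MAGNIFICATIONS: tuple[int, ...] = (40, 100, 200, 400)
CLASSES: tuple[str, str] = ("benign", "malignant")
BENIGN_SUBCLASSES: tuple[str, ...] = ("A", "F", "TA", "PT")
MALIGNANT_SUBCLASSES: tuple[str, ...] = ("DC", "LC", "MC", "PC")

SUBCLASS_TO_CLASS: dict[str, str] = {
    **{s: "benign" for s in BENIGN_SUBCLASSES},
    **{s: "malignant" for s in MALIGNANT_SUBCLASSES},
}

_MANIFEST_COLUMNS = [
    "image_id",
    "patient_id",
    "class_label",
    "subclass",
    "magnification",
    "source",
]

_BREAKHIS_RE = re.compile(
    r"^(?P<procedure>[A-Z]+)_(?P<cls>[BM])_(?P<subclass>[A-Z]+)"
    r"-(?P<year>\d+)-(?P<slide>[0-9A-Za-z]+)"
    r"-(?P<magnification>\d+)-(?P<seq>\d+)\.(png|PNG)$"
)


@dataclass(frozen=True)
class ImageRecord:
    """One histopathology patch with its labels and provenance.

    ``source`` is either a filesystem path to the image (str) or a row index
    into an accompanying feature table (int).
    """

    image_id: str
    patient_id: str
    class_label: str
    subclass: str
    magnification: int
    source: str | int = ""

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.subclass not in SUBCLASS_TO_CLASS:
            raise ValueError(f"unknown subclass {self.subclass!r}")
        if SUBCLASS_TO_CLASS[self.subclass] != self.class_label:
            raise ValueError(
                f"subclass {self.subclass!r} is inconsistent with class "
                f"{self.class_label!r}"
            )
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(
                f"magnification must be one of {MAGNIFICATIONS}, "
                f"got {self.magnification!r}"
            )


@dataclass
class Manifest:
    """An ordered collection of :class:`ImageRecord` with unique ids."""

    records: list[ImageRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate image_id {dup!r} in manifest")
        self._by_id = {r.image_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def __getitem__(self, image_id: str) -> ImageRecord:
        return self._by_id[image_id]

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._by_id

    @property
    def image_ids(self) -> list[str]:
        return [r.image_id for r in self.records]

    @property
    def patients(self) -> set[str]:
        return {r.patient_id for r in self.records}

    def labels(self, image_ids: Sequence[str] | None = None) -> list[str]:
        ids = self.image_ids if image_ids is None else image_ids
        return [self._by_id[i].class_label for i in ids]

    def patient_of(self, image_ids: Sequence[str] | None = None) -> list[str]:
        ids = self.image_ids if image_ids is None else image_ids
        return [self._by_id[i].patient_id for i in ids]

    def subset(self, image_ids: Iterable[str], provenance: str | None = None) -> "Manifest":
        wanted = set(image_ids)
        missing = wanted - set(self._by_id)
        if missing:
            raise KeyError(f"unknown image_id(s): {sorted(missing)[:5]}")
        recs = [r for r in self.records if r.image_id in wanted]
        return Manifest(recs, provenance or self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.image_id, r.patient_id, r.class_label, r.subclass,
                 r.magnification, r.source)
                for r in self.records
            ],
            columns=_MANIFEST_COLUMNS,
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_manifest(path: str | Path, provenance: str | None = None) -> Manifest:
    """Read a manifest written by :meth:`Manifest.write`.

    ``source`` values that look like integers are restored as feature-table
    row indices; everything else stays a string path.
    """
    df = pd.read_csv(path, dtype={"source": str}, keep_default_na=False)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        source: str | int = row.source
        if isinstance(source, str) and re.fullmatch(r"-?\d+", source):
            source = int(source)
        records.append(
            ImageRecord(
                image_id=str(row.image_id),
                patient_id=str(row.patient_id),
                class_label=str(row.class_label),
                subclass=str(row.subclass),
                magnification=int(row.magnification),
                source=source,
            )
        )
    return Manifest(records, provenance or f"read from {path}")


def parse_breakhis_filename(name: str) -> dict:
    """Decode one BreakHis-convention filename into its metadata tokens.

    Raises ``ValueError`` when the name does not follow the convention.
    """
    m = _BREAKHIS_RE.match(name)
    if m is None:
        raise ValueError(f"filename {name!r} does not follow the BreakHis convention")
    subclass = m.group("subclass")
    if subclass not in SUBCLASS_TO_CLASS:
        raise ValueError(f"filename {name!r}: unknown subclass token {subclass!r}")
    cls = "benign" if m.group("cls") == "B" else "malignant"
    if SUBCLASS_TO_CLASS[subclass] != cls:
        raise ValueError(
            f"filename {name!r}: class letter {m.group('cls')!r} contradicts "
            f"subclass {subclass!r}"
        )
    mag = int(m.group("magnification"))
    if mag not in MAGNIFICATIONS:
        raise ValueError(f"filename {name!r}: magnification {mag} not in {MAGNIFICATIONS}")
    return {
        "image_id": name.rsplit(".", 1)[0],
        "patient_id": f"{m.group('year')}-{m.group('slide')}",
        "class_label": cls,
        "subclass": subclass,
        "magnification": mag,
    }


def parse_breakhis_tree(root_path: str | Path) -> tuple[Manifest, list[str]]:
    """Scan a directory tree of BreakHis-named PNG images.

    Returns the manifest plus the list of files that did not match the naming
    convention (reported, never silently skipped). Raises ``ValueError`` when
    no image parses at all.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    records: list[ImageRecord] = []
    skipped: list[str] = []
    for path in sorted(root.rglob("*")):
        if not path.is_file() or path.suffix.lower() != ".png":
            continue
        try:
            meta = parse_breakhis_filename(path.name)
        except ValueError:
            skipped.append(str(path))
            continue
        records.append(ImageRecord(source=str(path), **meta))
    if not records:
        raise ValueError(
            f"no BreakHis-convention images found under {root} "
            f"({len(skipped)} non-matching files)"
        )
    prov = f"scanned {root} ({len(records)} images, {len(skipped)} skipped)"
    return Manifest(records, prov), skipped


@dataclass(frozen=True)
class FoldSplit:
    """One patient-disjoint train/test partition.

    ``scope`` is ``"MIB"`` (magnification-independent) or an int magnification
    for the magnification-specific regime.
    """

    fold_index: int
    train_ids: frozenset[str]
    test_ids: frozenset[str]
    scope: str | int = "MIB"

    def __post_init__(self) -> None:
        if self.scope != "MIB" and self.scope not in MAGNIFICATIONS:
            raise ValueError(f"scope must be 'MIB' or a magnification, got {self.scope!r}")


@dataclass
class FoldReport:
    """Outcome of validating one fold against a manifest."""

    passed: bool
    shared_patients: list[str] = field(default_factory=list)
    scope_violations: list[str] = field(default_factory=list)
    overlap_ids: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        if self.passed:
            return "PASS"
        parts = []
        if self.overlap_ids:
            parts.append(f"train/test image overlap: {self.overlap_ids}")
        if self.shared_patients:
            parts.append(f"patients on both sides: {self.shared_patients}")
        if self.scope_violations:
            parts.append(f"scope violations: {self.scope_violations}")
        return "FAIL (" + "; ".join(parts) + ")"


def validate_fold(split: FoldSplit, manifest: Manifest) -> FoldReport:
    """Check a fold for patient disjointness and magnification scope.

    Total on its domain: every (split, manifest) pair yields either a pass or
    a nonempty violation listing. Unknown image ids raise ``KeyError``.
    """
    unknown = (split.train_ids | split.test_ids) - set(manifest.image_ids)
    if unknown:
        raise KeyError(f"fold {split.fold_index}: unknown image_id(s) {sorted(unknown)[:5]}")
    overlap = sorted(split.train_ids & split.test_ids)
    train_patients = {manifest[i].patient_id for i in split.train_ids}
    test_patients = {manifest[i].patient_id for i in split.test_ids}
    shared = sorted(train_patients & test_patients)
    scope_bad: list[str] = []
    if split.scope != "MIB":
        scope_bad = sorted(
            i for i in (split.train_ids | split.test_ids)
            if manifest[i].magnification != split.scope
        )
    passed = not (overlap or shared or scope_bad)
    return FoldReport(passed, shared, scope_bad, overlap)


def restrict_to_magnification(manifest: Manifest, m: int) -> Manifest:
    """Keep only records at magnification ``m`` (idempotent filter)."""
    if m not in MAGNIFICATIONS:
        raise ValueError(f"magnification must be one of {MAGNIFICATIONS}, got {m!r}")
    recs = [r for r in manifest.records if r.magnification == m]
    return Manifest(recs, f"{manifest.provenance} | restricted to {m}x")


def restrict_fold(split: FoldSplit, manifest: Manifest, m: int) -> FoldSplit:
    """Scope a magnification-independent fold down to one magnification."""
    keep = {r.image_id for r in manifest.records if r.magnification == m}
    return FoldSplit(
        fold_index=split.fold_index,
        train_ids=frozenset(split.train_ids & keep),
        test_ids=frozenset(split.test_ids & keep),
        scope=m,
    )


def write_fold_files(folds: Sequence[FoldSplit], directory: str | Path) -> list[Path]:
    """Write each fold as two plain-text id lists (train/test), one id per line."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for f in folds:
        for side, ids in (("train", f.train_ids), ("test", f.test_ids)):
            p = directory / f"fold{f.fold_index}_{side}.txt"
            p.write_text("\n".join(sorted(ids)) + "\n")
            written.append(p)
    return written


def read_fold_files(
    directory: str | Path,
    fold_indices: Iterable[int] = (1, 2, 3, 4, 5),
    scope: str | int = "MIB",
) -> list[FoldSplit]:
    """Read per-fold train/test id list files written by :func:`write_fold_files`."""
    directory = Path(directory)
    folds = []
    for i in fold_indices:
        train_p = directory / f"fold{i}_train.txt"
        test_p = directory / f"fold{i}_test.txt"
        if not train_p.exists() or not test_p.exists():
            raise FileNotFoundError(f"missing fold file(s) for fold {i} under {directory}")
        folds.append(
            FoldSplit(
                fold_index=i,
                train_ids=frozenset(train_p.read_text().split()),
                test_ids=frozenset(test_p.read_text().split()),
                scope=scope,
            )
        )
    return folds


def read_fold_table(path: str | Path, scope: str | int = "MIB") -> list[FoldSplit]:
    """Read folds from a single CSV with columns image_id, fold, split(train|test)."""
    df = pd.read_csv(path)
    for col in ("image_id", "fold", "split"):
        if col not in df.columns:
            raise ValueError(f"fold table {path} lacks column {col!r}")
    folds = []
    for i, grp in df.groupby("fold"):
        folds.append(
            FoldSplit(
                fold_index=int(i),
                train_ids=frozenset(grp.loc[grp["split"] == "train", "image_id"].astype(str)),
                test_ids=frozenset(grp.loc[grp["split"] == "test", "image_id"].astype(str)),
                scope=scope,
            )
        )
    return sorted(folds, key=lambda f: f.fold_index)


def with_sources(manifest: Manifest, sources: Sequence[str | int]) -> Manifest:
    """Return a copy of the manifest with ``source`` replaced record-wise."""
    if len(sources) != len(manifest):
        raise ValueError("sources length must match manifest length")
    recs = [replace(r, source=s) for r, s in zip(manifest.records, sources)]
    return Manifest(recs, manifest.provenance)
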