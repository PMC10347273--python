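"""Frozen feature-extraction contract: image file -> fixed-length vector.

The pipeline never trains its convolutional feature extractor; it consumes a
frozen, deterministic map from a patch image to a 2048-dimensional vector
(the global-average-pool output of an ImageNet-pretrained ResNet152 in the
reference configuration). Everything downstream only sees feature tables, so
any object satisfying :class:`FeatureExtractor` can stand in.

Two extractors ship here:

* :class:`StubExtractor` — a deterministic hash-based extractor used to
  exercise the image-to-table path without a deep-learning runtime.
* :class:`PretrainedCNNExtractor` — the extension point for a real
  torchvision/keras backbone; it requires such a runtime at construction
  time and raises an informative error when none is importable.

Preprocessing follows the reference setup: resize to 224x224 before
extraction (recorded in the extractor's ``preprocessing`` string so that run
metadata is self-describing).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from PIL import Image

from .records import ImageRecord

RESIZE_TARGET = (224, 224)


@runtime_checkable
class FeatureExtractor(Protocol):
    name: str
    output_dim: int
    preprocessing: str

    def features_of(self, image: np.ndarray) -> np.ndarray:
        """Map one preprocessed HxWx3 uint8 array to an ``output_dim`` vector."""
        ...


def _load_and_preprocess(path: str | Path) -> np.ndarray:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"image file not found: {p}")
    try:
        with Image.open(p) as im:
            im = im.convert("RGB").resize(RESIZE_TARGET, Image.BILINEAR)
            return np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / corrupt image
        raise ValueError(f"cannot read image {p}: {exc}") from exc


def extract_features(
    extractor: FeatureExtractor, images: Sequence[ImageRecord]
) -> np.ndarray:
    """Extract one feature row per record, in input order.

    Rows are deterministic for a given extractor (frozen-extractor contract):
    repeated extraction of the same corpus yields bit-identical tables.
    """
    out = np.empty((len(images), extractor.output_dim), dtype=np.float64)
    for i, rec in enumerate(images):
        if not isinstance(rec.source, str) or not rec.source:
            raise TypeError(f"record {rec.image_id} carries no image path (source={rec.source!r})")
        arr = _load_and_preprocess(rec.source)
        vec = np.asarray(extractor.features_of(arr), dtype=np.float64)
        if vec.shape != (extractor.output_dim,):
            raise ValueError(
                f"extractor {extractor.name} returned shape {vec.shape}, "
                f"expected ({extractor.output_dim},) for {rec.image_id}"
            )
        out[i] = vec
    return out


@dataclass(frozen=True)
class StubExtractor:
    """Deterministic content-hash extractor for pipeline testing.

    The SHA-256 of the preprocessed pixel bytes, combined with ``seed``,
    seeds a PRNG that emits a standard-normal vector: identical images map to
    identical vectors, distinct images to (almost surely) distinct ones.
    Carries no visual semantics whatsoever.
    """

    seed: int = 0
    output_dim: int = 2048
    name: str = "stub"

    def __post_init__(self) -> None:
        if self.output_dim < 2:
            raise ValueError("output_dim must be >= 2")

    @property
    def preprocessing(self) -> str:
        return f"resize to {RESIZE_TARGET[0]}x{RESIZE_TARGET[1]} (bilinear), RGB uint8"

    def features_of(self, image: np.ndarray) -> np.ndarray:
        h = hashlib.sha256()
        h.update(np.int64(self.seed).tobytes())
        h.update(np.ascontiguousarray(image, dtype=np.uint8).tobytes())
        digest = np.frombuffer(h.digest(), dtype=np.uint64)
        rng = np.random.default_rng(digest)
        return rng.standard_normal(self.output_dim)


def stub_extractor(seed: int = 0, dim: int = 2048) -> StubExtractor:
    """Convenience constructor matching the module-level operation names."""
    return StubExtractor(seed=seed, output_dim=dim)


class PretrainedCNNExtractor:
    """Adapter for a real ImageNet-pretrained backbone (ResNet152 by default).

    Construction imports the deep-learning runtime; absence of one raises
    ``ImportError`` with guidance rather than failing later. Features are
    taken from the global-average-pool output (the 2048-unit layer) after the
    backbone's canonical ImageNet preprocessing.
    """

    output_dim = 2048

    def __init__(self, name: str = "resnet152") -> None:
        self.name = name
        self.preprocessing = (
            f"resize to {RESIZE_TARGET[0]}x{RESIZE_TARGET[1]}, canonical "
            "ImageNet normalization, global-average-pool tap"
        )
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "PretrainedCNNExtractor needs torch+torchvision; install them "
                "or precompute a feature table and feed it to the pipeline "
                "directly (the downstream contract is 'feature table in')."
            ) from exc
        import torch
        from torchvision import models, transforms

        weights = models.ResNet152_Weights.IMAGENET1K_V1
        net = models.resnet152(weights=weights)
        net.fc = torch.nn.Identity()
        net.eval()
        self._net = net
        self._torch = torch
        self._norm = transforms.Normalize(
            mean=[0.485, 0.456, 0.406], std=[0.229, 0.224, 0.225]
        )

    def features_of(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        x = torch.from_numpy(image.astype(np.float32) / 255.0).permute(2, 0, 1)
        x = self._norm(x).unsqueeze(0)
        with torch.no_grad():
            vec = self._net(x).squeeze(0).numpy()
        return vec.astype(np.float64)
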