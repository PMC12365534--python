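"""Patch featurization behind a pluggable backbone contract, plus the
per-slide HDF5 feature container.

A backbone is any callable mapping a batch of ``(N, 256, 256, 3)`` uint8
patches to ``(N, D)`` float vectors.  Real pretrained extractors (e.g. a
ResNet50 trunk producing 1,024-d vectors) are registered as plug-ins;
the built-in ``synthetic`` backbone is a content-hash-seeded random
projection that is fully deterministic in the pixel values, which is all
the desk-scale pipeline and tests need.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import h5py
import numpy as np

from .errors import ContractViolationError, EmptyBagError, FormatError, InvalidInputError
from .slides import PatchGrid, SlideImage, coord_checksum

SCHEMA_VERSION = "gastromil-bag-1"


def synthetic_featurizer(patch: np.ndarray, dim: int = 1024, seed_salt: str = "") -> np.ndarray:
    """Deterministic pseudo-feature for one patch.

    The SHA-256 of the raw pixel bytes (plus shape and salt) seeds a
    generator that draws a standard-normal vector, so identical pixels
    always map to identical vectors and any pixel change re-seeds the
    draw entirely.
    """
    if dim < 1:
        raise InvalidInputError("feature dimension must be >= 1")
    arr = np.ascontiguousarray(patch)
    h = hashlib.sha256()
    h.update(seed_salt.encode())
    h.update(str(arr.shape).encode())
    h.update(arr.tobytes())
    seed = int.from_bytes(h.digest()[:8], "little") % (2**32)
    vec = np.random.default_rng(seed).standard_normal(dim).astype(np.float32)
    return vec


@dataclass
class BackboneContract:
    """Featurizer contract: fixed input patch size, fixed output length."""

    name: str
    dim: int
    fn: Callable[[np.ndarray], np.ndarray]
    input_size: tuple[int, int, int] = (256, 256, 3)
    deterministic: bool = True

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        out = np.asarray(self.fn(batch), dtype=np.float32)
        if out.shape != (len(batch), self.dim):
            raise ContractViolationError(
                f"backbone '{self.name}' returned shape {out.shape}, "
                f"expected {(len(batch), self.dim)}"
            )
        return out


_REGISTRY: dict[str, Callable[[int], BackboneContract]] = {}


def register_backbone(name: str, factory: Callable[[int], BackboneContract]) -> None:
    """Register a plug-in backbone factory keyed by name."""
    _REGISTRY[name] = factory


def get_backbone(name: str, dim: int = 1024) -> BackboneContract:
    if name == "synthetic":
        def _batch(batch: np.ndarray) -> np.ndarray:
            return np.stack([synthetic_featurizer(p, dim) for p in batch])

        return BackboneContract(name="synthetic", dim=dim, fn=_batch)
    if name in _REGISTRY:
        return _REGISTRY[name](dim)
    raise InvalidInputError(f"unknown backbone '{name}'")


@dataclass
class FeatureBag:
    """One slide as an M x D feature matrix aligned to patch coordinates."""

    slide_id: str
    features: np.ndarray
    coords: np.ndarray
    backbone: str = "synthetic"
    magnification: float = 40.0
    patch_span_base: int = 256

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.features.ndim != 2 or len(self.features) < 1:
            raise EmptyBagError("feature bag needs an (M >= 1) x D matrix")
        if self.coords.shape != (len(self.features), 2):
            raise ContractViolationError("coords must align with feature rows")
        if not np.isfinite(self.features).all():
            raise InvalidInputError("feature matrix contains non-finite values")

    @property
    def n_instances(self) -> int:
        return len(self.features)

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def extract_features(
    grid: PatchGrid,
    slide: SlideImage,
    backbone: BackboneContract,
    batch_size: int = 32,
) -> FeatureBag:
    """Featurize every retained patch, rows in grid order.

    Batching is a throughput knob only: results are identical for any
    ``batch_size`` because the backbone contract is row-wise.
    """
    if len(grid) == 0:
        raise EmptyBagError(f"grid for slide '{grid.slide_id}' has no patches")
    if batch_size < 1:
        raise InvalidInputError("batch_size must be >= 1")
    span = grid.span_base
    coords = grid.coords
    rows: list[np.ndarray] = []
    for start in range(0, len(coords), batch_size):
        chunk = coords[start : start + batch_size]
        patches = np.stack(
            [slide.read_patch(int(x), int(y), span, grid.level, grid.patch_size_px) for x, y in chunk]
        )
        rows.append(backbone(patches))
    return FeatureBag(
        slide_id=grid.slide_id,
        features=np.concatenate(rows, axis=0),
        coords=coords,
        backbone=backbone.name,
        magnification=grid.magnification,
        patch_span_base=span,
    )


def save_bag(bag: FeatureBag, path: str | Path) -> None:
    """Append one slide's bag to an HDF5 container (group per slide)."""
    with h5py.File(path, "a") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        if bag.slide_id in f:
            del f[bag.slide_id]
        g = f.create_group(bag.slide_id)
        g.create_dataset("features", data=bag.features)
        g.create_dataset("coords", data=bag.coords)
        g.attrs["backbone"] = bag.backbone
        g.attrs["magnification"] = bag.magnification
        g.attrs["patch_span_base"] = bag.patch_span_base
        g.attrs["coord_sha256"] = coord_checksum(bag.coords)


def list_slides(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(f.keys())


def load_bag(path: str | Path, slide_id: str | None = None) -> FeatureBag:
    """Load one bag; verifies schema version and coordinate checksum."""
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("schema") != SCHEMA_VERSION:
                raise FormatError(
                    f"container schema {f.attrs.get('schema')!r} != {SCHEMA_VERSION!r}"
                )
            sid = slide_id or sorted(f.keys())[0]
            if sid not in f:
                raise FormatError(f"slide '{sid}' not in container")
            g = f[sid]
            feats = g["features"][...]
            coords = g["coords"][...]
            if g.attrs["coord_sha256"] != coord_checksum(coords):
                raise FormatError("coordinate checksum mismatch; container corrupt")
            return FeatureBag(
                slide_id=sid,
                features=feats,
                coords=coords,
                backbone=str(g.attrs["backbone"]),
                magnification=float(g.attrs["magnification"]),
                patch_span_base=int(g.attrs["patch_span_base"]),
            )
    except OSError as exc:  # truncated / not an HDF5 file
        raise FormatError(f"cannot read feature container {path}: {exc}") from exc
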