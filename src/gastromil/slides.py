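"""Slide loading, tissue segmentation and foreground tiling.

A whole-slide image is modelled as a small pyramid of RGB arrays with
microns-per-pixel metadata.  Plain PNG/TIFF files are treated as
single-level slides at a declared objective power, which keeps the whole
pipeline exercisable on synthetic fixtures; multi-page TIFFs are read as
pyramids (page 0 = base).  Patch coordinates are always expressed in
base-level pixels, 0-based, half-open, so downstream heatmaps have a
single unambiguous frame regardless of the working magnification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.transform import resize

from .errors import InvalidInputError, UnsupportedMagnificationError

PATCH_SIZE = 256


@dataclass
class SlideImage:
    """An RGB slide pyramid with base-level resolution metadata.

    Parameters
    ----------
    slide_id:
        Stable identifier, used to key feature bags and predictions.
    levels:
        Pyramid levels ordered base -> coarsest; each an ``(H, W, 3)``
        uint8 array.
    mpp_x, mpp_y:
        Microns per pixel at the base level (e.g. 0.086 for a 40x scan
        on a Zeiss Axio Scan 7).
    base_magnification:
        Nominal objective power of the base level.
    """

    slide_id: str
    levels: list[np.ndarray]
    mpp_x: float = 0.25
    mpp_y: float = 0.25
    base_magnification: float = 40.0

    def __post_init__(self) -> None:
        if not self.levels:
            raise InvalidInputError("slide needs at least one pyramid level")
        if self.mpp_x <= 0 or self.mpp_y <= 0:
            raise InvalidInputError("microns-per-pixel must be positive")
        for lv in self.levels:
            if lv.ndim != 3 or lv.shape[2] != 3:
                raise InvalidInputError("levels must be (H, W, 3) RGB arrays")
        shapes = [lv.shape[:2] for lv in self.levels]
        if shapes != sorted(shapes, key=lambda s: -s[0] * s[1]):
            raise InvalidInputError("levels must be ordered base -> coarsest")

    @property
    def dimensions(self) -> tuple[int, int]:
        """Base-level (height, width)."""
        return self.levels[0].shape[:2]

    @property
    def level_downsamples(self) -> list[float]:
        h0 = self.levels[0].shape[0]
        return [h0 / lv.shape[0] for lv in self.levels]

    @classmethod
    def from_array(
        cls,
        array: np.ndarray,
        slide_id: str = "slide",
        mpp: float = 0.25,
        magnification: float = 40.0,
    ) -> "SlideImage":
        """Wrap a single in-memory RGB array as a one-level slide."""
        arr = np.asarray(array)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        return cls(slide_id, [arr.astype(np.uint8)], mpp, mpp, magnification)

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        slide_id: str | None = None,
        mpp: float = 0.25,
        magnification: float = 40.0,
    ) -> "SlideImage":
        """Read a PNG or (possibly multi-page) TIFF as a slide.

        A multi-page TIFF whose pages shrink monotonically is treated as
        a pyramid; anything else is a single-level slide at the declared
        magnification.
        """
        path = Path(path)
        sid = slide_id or path.stem
        if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
            import tifffile

            with tifffile.TiffFile(path) as tf:
                pages = [p.asarray() for p in tf.pages]
            pages = [p for p in pages if p.ndim >= 2]
            levels = []
            for p in pages:
                if p.ndim == 2:
                    p = np.stack([p] * 3, axis=-1)
                levels.append(p[..., :3].astype(np.uint8))
            levels.sort(key=lambda a: -a.shape[0] * a.shape[1])
        else:
            from PIL import Image

            with Image.open(path) as im:
                levels = [np.asarray(im.convert("RGB"), dtype=np.uint8)]
        return cls(sid, levels, mpp, mpp, magnification)

    def read_region(self, x: int, y: int, w: int, h: int, level: int = 0) -> np.ndarray:
        """Crop ``[y:y+h, x:x+w]`` of *level*, coordinates in that level's pixels."""
        lv = self.levels[level]
        if x < 0 or y < 0 or x + w > lv.shape[1] or y + h > lv.shape[0]:
            raise InvalidInputError("region outside slide bounds")
        return lv[y : y + h, x : x + w]

    def read_patch(self, x: int, y: int, span: int, level: int, out_size: int = PATCH_SIZE) -> np.ndarray:
        """Read a base-coordinate patch of side ``span`` base px via *level*.

        The patch is resized to ``out_size`` if the level pixels do not
        match it exactly (non power-of-two requests).
        """
        ds = self.level_downsamples[level]
        xl, yl, sl = round(x / ds), round(y / ds), round(span / ds)
        region = self.read_region(xl, yl, sl, sl, level)
        if sl != out_size:
            region = resize(
                region, (out_size, out_size), order=1, preserve_range=True, anti_aliasing=False
            ).astype(np.uint8)
        return region


@dataclass
class TissueMask:
    """Binary foreground mask at a stated downsample of the base level."""

    mask: np.ndarray
    downsample: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise InvalidInputError("mask must be 2-D")
        if self.downsample < 1:
            raise InvalidInputError("downsample must be a positive integer")

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray((self.mask * 255).astype(np.uint8)).save(path)


@dataclass
class SegmentationConfig:
    """Knobs of the saturation/Otsu tissue detector.

    ``saturation_floor`` is the absolute HSV-saturation used when the
    thumbnail is (near-)constant and Otsu is meaningless; ``median_size``
    and ``min_object_px`` despeckle the thresholded mask.  Setting
    ``median_size=1`` and ``min_object_px=0`` disables smoothing, which
    makes the detector a pure per-pixel threshold.
    """

    saturation_floor: float = 0.05
    median_size: int = 5
    min_object_px: int = 64


def segment_tissue(
    slide: SlideImage, downsample: int = 32, config: SegmentationConfig | None = None
) -> TissueMask:
    """Isolate tissue from glass background on a thumbnail.

    Background (near-white, low-saturation) pixels are 0.  The detector
    thresholds the HSV saturation channel with Otsu, then applies a
    median filter and removes small connected components.
    """
    config = config or SegmentationConfig()
    base = slide.levels[0]
    thumb = base[::downsample, ::downsample]
    if thumb.shape[0] < 16 or thumb.shape[1] < 16:
        raise InvalidInputError(
            f"downsample {downsample} yields a {thumb.shape[0]}x{thumb.shape[1]} "
            "thumbnail; need at least 16x16"
        )
    sat = rgb2hsv(thumb)[..., 1]
    if sat.max() - sat.min() < 1e-3:
        # constant-saturation image: Otsu undefined, fall back to the floor
        mask = sat >= config.saturation_floor
    else:
        thr = max(threshold_otsu(sat), config.saturation_floor)
        mask = sat > thr
    if config.median_size > 1:
        mask = median_filter(mask, size=config.median_size)
    if config.min_object_px > 0:
        mask = remove_small_objects(mask, max_size=config.min_object_px - 1)
    return TissueMask(mask, downsample)


def select_working_level(slide: SlideImage, magnification: float) -> tuple[int, float]:
    """Map a requested objective power to (pyramid level, extra resize factor).

    Picks the finest stored level at least as detailed as the request;
    the returned factor is the residual downscale to apply to that
    level's pixels (1.0 when a stored level matches exactly).
    """
    if magnification > slide.base_magnification:
        raise UnsupportedMagnificationError(
            f"requested {magnification}x exceeds base {slide.base_magnification}x"
        )
    if magnification <= 0:
        raise InvalidInputError("magnification must be positive")
    total_ds = slide.base_magnification / magnification
    level = 0
    for i, ds in enumerate(slide.level_downsamples):
        if ds <= total_ds + 1e-9:
            level = i
    return level, total_ds / slide.level_downsamples[level]


@dataclass
class PatchGrid:
    """Non-overlapping 256 px patch lattice over the tissue foreground.

    Coordinates are top-left corners in base-level pixels; each patch
    spans ``patch_size_px * scale`` base pixels where ``scale`` is the
    base-to-working-magnification factor.
    """

    slide_id: str
    magnification: float
    level: int
    scale: float  # base px spanned per working-level px
    patch_size_px: int = PATCH_SIZE
    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["x", "y", "foreground_fraction"])
    )

    def __post_init__(self) -> None:
        req = {"x", "y", "foreground_fraction"}
        if not req.issubset(self.records.columns):
            raise InvalidInputError(f"grid records need columns {sorted(req)}")
        self._assert_non_overlapping()

    def _assert_non_overlapping(self) -> None:
        span = self.span_base
        xy = self.records[["x", "y"]].to_numpy()
        if len(xy) == 0:
            return
        # lattice alignment (stride == span) makes overlap equivalent to
        # duplicate corners or off-lattice coordinates
        if len(np.unique(xy, axis=0)) != len(xy) or (xy % span).any():
            raise InvalidInputError("patch rectangles overlap or are off-lattice")

    @property
    def span_base(self) -> int:
        """Base pixels covered by one patch edge."""
        return int(round(self.patch_size_px * self.scale))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coords(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=np.int64)

    def to_csv(self, path: str | Path) -> None:
        out = self.records.copy()
        out.insert(0, "slide_id", self.slide_id)
        out["level"] = self.level
        out.to_csv(path, index=False, float_format="%.6f")

    def sidecar(self) -> dict:
        payload = {
            "slide_id": self.slide_id,
            "magnification": self.magnification,
            "level": self.level,
            "scale": self.scale,
            "patch_size_px": self.patch_size_px,
            "n_patches": len(self),
            "coord_sha256": coord_checksum(self.coords),
        }
        return payload

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(), indent=2, sort_keys=True))

    @classmethod
    def from_csv(
        cls, path: str | Path, magnification: float, scale: float, patch_size_px: int = PATCH_SIZE
    ) -> "PatchGrid":
        df = pd.read_csv(path)
        sid = str(df["slide_id"].iloc[0]) if len(df) else "slide"
        level = int(df["level"].iloc[0]) if len(df) else 0
        return cls(
            slide_id=sid,
            magnification=magnification,
            level=level,
            scale=scale,
            patch_size_px=patch_size_px,
            records=df[["x", "y", "foreground_fraction"]].reset_index(drop=True),
        )


def coord_checksum(coords: np.ndarray) -> str:
    """Order-sensitive checksum tying feature rows to grid coordinates."""
    return hashlib.sha256(np.ascontiguousarray(coords, dtype=np.int64).tobytes()).hexdigest()


def tile_foreground(
    slide: SlideImage,
    mask: TissueMask,
    magnification: float | None = None,
    min_foreground: float = 0.5,
    patch_size: int = PATCH_SIZE,
) -> PatchGrid:
    """Enumerate the non-overlapping patch lattice and keep tissue patches.

    The lattice has stride ``patch_size`` at the working magnification
    (``patch_size * scale`` base pixels); a patch is retained when the
    fraction of mask-positive pixels under it reaches ``min_foreground``.
    """
    magnification = magnification or slide.base_magnification
    level, extra = select_working_level(slide, magnification)
    scale = slide.base_magnification / magnification
    if not 0.0 <= min_foreground <= 1.0:
        raise InvalidInputError("min_foreground must lie in [0, 1]")
    h0, w0 = slide.dimensions
    span = int(round(patch_size * scale))
    d = mask.downsample
    m = mask.mask
    rows = []
    for y in range(0, h0 - span + 1, span):
        for x in range(0, w0 - span + 1, span):
            sub = m[y // d : max(y // d + 1, (y + span) // d), x // d : max(x // d + 1, (x + span) // d)]
            frac = float(sub.mean()) if sub.size else 0.0
            if frac >= min_foreground:
                rows.append((x, y, frac))
    df = pd.DataFrame(rows, columns=["x", "y", "foreground_fraction"])
    return PatchGrid(
        slide_id=slide.slide_id,
        magnification=magnification,
        level=level,
        scale=scale,
        patch_size_px=patch_size,
        records=df,
    )
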