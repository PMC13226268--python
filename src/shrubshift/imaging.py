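"""Core raster and mask types shared by every stage of the toolkit.

All pixel intensities live on a normalized real [0, 1] scale internally,
whatever the bit depth of the file they came from; 8-bit and 16-bit files
are rescaled on read and re-quantized on write.  Coordinates are 0-based,
half-open, row-major ``(y, x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

#: Canonical output raster size as (width, height) in pixels.
CANONICAL_SIZE = (1184, 864)

#: Ordered class set of the scene-parsing probability stack.
CLASS_NAMES = ("soil", "sky", "grass", "target_shrub")


class ChannelLayout(str, Enum):
    GRAY = "GRAY"
    RGB = "RGB"
    RGBA = "RGBA"


_LAYOUT_CHANNELS = {ChannelLayout.GRAY: 1, ChannelLayout.RGB: 3, ChannelLayout.RGBA: 4}

#: Rec.601 luma coefficients used for every luminance reduction.
REC601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RasterImage:
    """A channelled pixel grid with intensities in [0, 1].

    ``pixels`` has shape (height, width) for GRAY and (height, width, C)
    for RGB/RGBA.  RGBA alpha is a validity channel: pixels with alpha 0
    are excluded from all region statistics downstream.
    """

    pixels: np.ndarray
    layout: ChannelLayout

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        n_ch = 1 if px.ndim == 2 else px.shape[2]
        if _LAYOUT_CHANNELS[self.layout] != n_ch:
            raise ValueError(
                f"layout {self.layout.value} expects {_LAYOUT_CHANNELS[self.layout]} "
                f"channels, got {n_ch}"
            )
        if px.ndim == 2 and self.layout is not ChannelLayout.GRAY:
            raise ValueError("2-D pixel grid must use GRAY layout")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("raster must be at least 1x1")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def luminance(self) -> np.ndarray:
        """Rec.601 luminance, or the single channel for GRAY rasters."""
        if self.layout is ChannelLayout.GRAY:
            return self.pixels
        return self.pixels[..., :3] @ REC601

    def rgb(self) -> np.ndarray:
        """(H, W, 3) view of the color content; GRAY is replicated."""
        if self.layout is ChannelLayout.GRAY:
            return np.repeat(self.pixels[..., None], 3, axis=2)
        return self.pixels[..., :3]

    def validity(self) -> np.ndarray:
        """Boolean per-pixel validity; False where RGBA alpha is 0."""
        if self.layout is ChannelLayout.RGBA:
            return self.pixels[..., 3] > 0
        return np.ones(self.shape, dtype=bool)


class MaskRole(str, Enum):
    BUSH = "bush"
    BACKGROUND = "background"
    EXCLUSION = "exclusion"
    OTHER = "other"


@dataclass(frozen=True)
class RegionMask:
    """A [0, 1]-weighted region aligned to a raster.

    Binary masks are the special case where every weight is exactly 0 or
    1; feathered masks carry graded weights that act as statistical
    weights downstream.
    """

    weights: np.ndarray
    role: MaskRole = MaskRole.OTHER

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2:
            raise ValueError("mask weights must be a 2-D grid")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("mask weights must lie in [0, 1]")
        object.__setattr__(self, "weights", np.clip(w, 0.0, 1.0))

    @property
    def binary_flag(self) -> bool:
        w = self.weights
        return bool(np.all((w == 0.0) | (w == 1.0)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def as_bool(self, threshold: float = 0.5) -> np.ndarray:
        return self.weights >= threshold if not self.binary_flag else self.weights > 0

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def with_role(self, role: MaskRole) -> "RegionMask":
        return replace(self, role=role)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based, half-open [min, max)."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate bounding box {self}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError("bounding box coordinates must be non-negative")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) in continuous pixel coordinates."""
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


@dataclass(frozen=True)
class ClassProbabilityStack:
    """Per-pixel probabilities for the ordered classes soil/sky/grass/target_shrub.

    This is an ingestion contract: any scene parser may produce it.  The
    per-pixel probabilities must sum to 1 within 1e-6.
    """

    probs: np.ndarray  # (H, W, 4)
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if p.ndim != 3 or p.shape[2] != len(self.class_names):
            raise ValueError(f"probability stack must be (H, W, {len(self.class_names)})")
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = p.sum(axis=2)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("per-pixel class probabilities must sum to 1 within 1e-6")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]

    def layer(self, name: str) -> np.ndarray:
        try:
            idx = self.class_names.index(name)
        except ValueError:
            raise KeyError(f"no class layer named {name!r}") from None
        return self.probs[..., idx]


@dataclass(frozen=True)
class ScenePair:
    """An original/reconstructed raster pair sharing one vegetation mask.

    The unit of paired assessment: the reconstruction is expected to
    preserve the target-shrub pixels while restructuring the background.
    """

    original: RasterImage
    reconstructed: RasterImage
    bush_mask: RegionMask
    pair_id: str = ""
    class_label: str = ""
    class_probs: Optional[ClassProbabilityStack] = None

    def __post_init__(self):
        if not (self.original.shape == self.reconstructed.shape == self.bush_mask.shape):
            raise ValueError("pair members must share identical spatial dims")
        if self.class_probs is not None and self.class_probs.shape != self.original.shape:
            raise ValueError("probability stack dims must match the rasters")
        if self.bush_mask.total_weight() <= 0:
            raise ValueError("bush mask must contain at least one positive pixel")


# ---------------------------------------------------------------------------
# I/O


def _normalize_loaded(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise ValueError(f"unsupported pixel dtype {arr.dtype}")


def read_raster(path: str | Path) -> RasterImage:
    """Read a PNG or TIFF raster and normalize intensities to [0, 1]."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 2:  # gray+alpha: promote alpha
        gray, alpha = arr[..., 0], arr[..., 1]
        arr = np.stack([gray, gray, gray, alpha], axis=2)
    if arr.ndim == 2:
        layout = ChannelLayout.GRAY
    elif arr.ndim == 3 and arr.shape[2] == 3:
        layout = ChannelLayout.RGB
    elif arr.ndim == 3 and arr.shape[2] == 4:
        layout = ChannelLayout.RGBA
    else:
        raise ValueError(f"unsupported channel count in {path}")
    return RasterImage(_normalize_loaded(arr), layout)


def _quantize(pixels: np.ndarray, bit_depth: int) -> np.ndarray:
    vmax = 2**bit_depth - 1
    # round-half-up so that 0.5 at 8 bit stores byte 128
    q = np.floor(np.clip(pixels, 0.0, 1.0) * vmax + 0.5)
    return q.astype(np.uint8 if bit_depth == 8 else np.uint16)


def write_raster(image: RasterImage, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a raster as PNG (8-bit) or TIFF (8/16-bit).

    Round-tripping through :func:`read_raster` reproduces intensities
    within one quantization step, ``1 / (2**bit_depth - 1)``.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    arr = _quantize(image.pixels, bit_depth)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if bit_depth == 16:
            raise ValueError("16-bit output requires a TIFF path")
        iio.imwrite(path, arr)
    return path


def read_mask(path: str | Path, role: MaskRole = MaskRole.OTHER) -> RegionMask:
    """Read a single-channel PNG mask; 0 = outside, full scale = inside."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"mask file must be single-channel: {path}")
    return RegionMask(_normalize_loaded(arr), role=role)


def write_mask(mask: RegionMask, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, _quantize(mask.weights, 8))
    return path


def complement_mask(mask: RegionMask) -> RegionMask:
    """1 - weights; the bush/background roles flip into each other."""
    flip = {MaskRole.BUSH: MaskRole.BACKGROUND, MaskRole.BACKGROUND: MaskRole.BUSH}
    return RegionMask(1.0 - mask.weights, role=flip.get(mask.role, mask.role))


def read_probability_stack(path: str | Path) -> ClassProbabilityStack:
    """Read a class-probability stack from a multi-page 16-bit TIFF."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 3:
        raise ValueError("probability TIFF must have one page per class")
    if arr.shape[0] == len(CLASS_NAMES):  # pages-first
        arr = np.moveaxis(arr, 0, 2)
    probs = arr.astype(np.float64) / 65535.0
    probs = probs / probs.sum(axis=2, keepdims=True)
    return ClassProbabilityStack(probs)


def write_probability_stack(stack: ClassProbabilityStack, path: str | Path) -> Path:
    path = Path(path)
    pages = np.moveaxis(_quantize(stack.probs, 16), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Pair manifests


def load_manifest(path: str | Path) -> list[ScenePair]:
    """Load scene pairs from a JSON manifest.

    The manifest is a JSON array of objects with keys ``pair_id``,
    ``class_label``, ``original_path``, ``reconstructed_path``,
    ``bush_mask_path`` and optional ``class_probs_path``; relative paths
    resolve against the manifest's directory.
    """
    path = Path(path)
    records = json.loads(path.read_text())
    base = path.parent
    pairs = []
    for rec in records:
        def _p(key):
            return base / rec[key] if not Path(rec[key]).is_absolute() else Path(rec[key])

        probs = None
        if rec.get("class_probs_path"):
            probs = read_probability_stack(_p("class_probs_path"))
        pairs.append(
            ScenePair(
                original=read_raster(_p("original_path")),
                reconstructed=read_raster(_p("reconstructed_path")),
                bush_mask=read_mask(_p("bush_mask_path"), role=MaskRole.BUSH),
                pair_id=str(rec["pair_id"]),
                class_label=str(rec.get("class_label", "")),
                class_probs=probs,
            )
        )
    return pairs
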