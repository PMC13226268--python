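"""Deterministic vegetation-prior refinement pipeline.

Turns an input raster plus a four-class probability stack into a
refined, standardized, annotation-ready vegetation prior through four
sequential stages: scene-parsing thresholds and exclusion-mask
construction (stage 1), boundary refinement by edge and color-cluster
analysis (stage 2), shadow/soil radiometric correction (stage 3), and
output standardization to the canonical raster contract (stage 4).

Every operator is a pure function of its inputs and the configuration;
the single stochastic step (k-means color clustering) takes an explicit
seed, so the whole pipeline is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import yaml
from scipy import ndimage
from skimage import feature, measure, transform
from skimage.draw import polygon2mask
from sklearn.cluster import KMeans

from .imaging import (
    CANONICAL_SIZE,
    BoundingBox,
    ChannelLayout,
    ClassProbabilityStack,
    MaskRole,
    RasterImage,
    RegionMask,
    ScenePair,
)

STAGE_ORDER = (
    "1.1", "1.2", "1.3", "1.4",
    "2.1", "2.2", "2.3",
    "3.1", "3.2", "3.3", "3.4",
    "4.1", "4.2", "4.3",
)


@dataclass(frozen=True)
class RefinementConfig:
    """All tunable parameters of the four refinement stages.

    Thresholds are on the normalized [0, 1] intensity/probability scale
    except the edge-detector pair (``canny_low``, ``canny_high``), which
    is conventionally stated on the 8-bit 0-255 luminance scale.
    """

    # stage 1.1 — localization box and binary foreground decision
    box_scale_factor: float = 0.8
    num_classes: int = 2
    target_threshold: float = 0.6
    # stage 1.3 — exclusion thresholds per non-target class
    soil_thresh: float = 0.7
    sky_thresh: float = 0.8
    grass_thresh: float = 0.6
    # stage 1.4 — morphological cleanup
    stage1_kernel: tuple[int, int] = (3, 3)
    stage1_iterations: int = 1
    # stage 2.1 — edge-guided contour refinement
    canny_low: float = 50.0
    canny_high: float = 150.0
    stage2_kernel: tuple[int, int] = (3, 3)
    stage2_iterations: int = 2
    epsilon_fraction: float = 0.01
    # stage 2.2 — color-cluster refinement
    n_clusters: int = 5
    random_state: int = 42
    cluster_overlap_threshold: float = 0.1
    # stage 2.3
    feather_radius_stage2: float = 3.0
    # stage 3.1 — shadow correction
    shadow_threshold: float = 0.3
    luminance_weight: float = 0.7
    brighten_factor: float = 1.3
    blend_sigma: float = 2.0
    # stage 3.2 — soil color correction
    color_tolerance: float = 0.1
    correction_strength: float = 0.5
    soil_endmember_threshold: float = 0.2
    # stage 3.3 — soil suppression band
    suppression_radius: int = 3
    suppression_strength: float = 0.8
    # stage 3.4
    stage3_kernel: tuple[int, int] = (3, 3)
    stage3_iterations: int = 1
    # stage 4.1 — upscale + unsharp
    upscale_factor: float = 4.0
    upscaler_name: str = "bicubic"
    unsharp_amount: float = 1.2
    unsharp_radius: float = 0.5
    unsharp_threshold: float = 0.0
    sharpen_strength: float = 0.6
    # stage 4.2 — crop and standardize
    crop_scale_factor: float = 1.5
    interpolation: str = "bicubic"
    centering: str = "center_of_mass"
    padding_fraction: float = 0.1
    aspect_ratio: float = 1.1  # width : height
    # stage 4.3 — output composition
    alpha_channel: bool = True
    feather_radius_output: float = 2.0
    canonical_size: tuple[int, int] = CANONICAL_SIZE  # (width, height)

    def __post_init__(self):
        for name in ("target_threshold", "soil_thresh", "sky_thresh", "grass_thresh",
                     "shadow_threshold", "cluster_overlap_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("stage1_kernel", "stage2_kernel", "stage3_kernel"):
            k = getattr(self, name)
            if any(d <= 0 or d % 2 == 0 for d in k):
                raise ValueError(f"{name} dims must be odd and positive, got {k}")
        for name in ("stage1_iterations", "stage2_iterations", "stage3_iterations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        for name in ("box_scale_factor", "brighten_factor", "upscale_factor",
                     "crop_scale_factor", "aspect_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# Mapping from stage-grouped YAML keys (parameter names as conventionally
# printed) to RefinementConfig fields.
_YAML_KEY_MAP: dict[str, dict[str, str]] = {
    "stage_1_1": {"box_scale_factor": "box_scale_factor",
                  "num_classes": "num_classes", "threshold": "target_threshold"},
    "stage_1_3": {"soil_thresh": "soil_thresh", "sky_thresh": "sky_thresh",
                  "grass_thresh": "grass_thresh"},
    "stage_1_4": {"kernel_size": "stage1_kernel", "iterations": "stage1_iterations"},
    "stage_2_1": {"low_thresh": "canny_low", "high_thresh": "canny_high",
                  "kernel_size": "stage2_kernel", "iterations": "stage2_iterations",
                  "epsilon": "epsilon_fraction"},
    "stage_2_2": {"n_clusters": "n_clusters", "random_state": "random_state",
                  "threshold": "cluster_overlap_threshold"},
    "stage_2_3": {"feather_radius": "feather_radius_stage2"},
    "stage_3_1": {"shadow_threshold": "shadow_threshold",
                  "luminance_weight": "luminance_weight",
                  "brighten_factor": "brighten_factor", "blend_sigma": "blend_sigma"},
    "stage_3_2": {"color_tolerance": "color_tolerance",
                  "correction_strength": "correction_strength",
                  "soil_endmember_threshold": "soil_endmember_threshold"},
    "stage_3_3": {"suppression_radius": "suppression_radius",
                  "strength": "suppression_strength"},
    "stage_3_4": {"kernel_size": "stage3_kernel", "iterations": "stage3_iterations"},
    "stage_4_1": {"upscale_factor": "upscale_factor", "model_name": "upscaler_name",
                  "amount": "unsharp_amount", "radius": "unsharp_radius",
                  "threshold": "unsharp_threshold", "strength": "sharpen_strength"},
    "stage_4_2": {"scale_factor": "crop_scale_factor",
                  "interpolation": "interpolation", "method": "centering",
                  "padding": "padding_fraction", "aspect_ratio": "aspect_ratio"},
    "stage_4_3": {"alpha_channel": "alpha_channel",
                  "feather_radius": "feather_radius_output"},
    "input": {"canonical_size": "canonical_size"},
}


def load_config(path: str | Path) -> RefinementConfig:
    """Load a stage-grouped YAML configuration; unknown keys are an error."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for stage_key, params in data.items():
        if stage_key not in _YAML_KEY_MAP:
            raise KeyError(f"unknown config section {stage_key!r}")
        for pname, value in (params or {}).items():
            try:
                fname = _YAML_KEY_MAP[stage_key][pname.lower()]
            except KeyError:
                raise KeyError(f"unknown parameter {pname!r} in {stage_key}") from None
            if isinstance(value, list):
                value = tuple(value)
            kwargs[fname] = value
    return RefinementConfig(**kwargs)


@dataclass
class TraceRecord:
    stage_id: str
    operator: str
    pixels_in: int
    pixels_out: int
    params: dict


@dataclass
class RefinementTrace:
    """Ordered audit record of every stage applied in a refinement run."""

    records: list[TraceRecord] = field(default_factory=list)

    def add(self, stage_id: str, operator: str, pixels_in: int, pixels_out: int,
            **params) -> None:
        self.records.append(TraceRecord(stage_id, operator, int(pixels_in),
                                        int(pixels_out), params))

    def stage_ids(self) -> list[str]:
        return [r.stage_id for r in self.records]

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(dataclasses.asdict(r), default=str)
                         for r in self.records)


# ---------------------------------------------------------------------------
# helpers


def _round_away(x: float) -> int:
    """Round half away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _footprint(kernel: tuple[int, int]) -> np.ndarray:
    return np.ones(kernel, dtype=bool)


def _binary(mask: RegionMask) -> np.ndarray:
    if not mask.binary_flag:
        raise ValueError("operation requires a binary mask")
    return mask.weights > 0


# ---------------------------------------------------------------------------
# stage 1 operators


def scale_box(box: BoundingBox, factor: float,
              image_size: Optional[tuple[int, int]] = None) -> BoundingBox:
    """Scale a box about its center, round, and clamp to the image.

    ``image_size`` is (width, height); omit to skip clamping.  Raises if
    the scaled-and-clamped box collapses to zero area.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    cx, cy = box.center
    hw, hh = box.width * factor / 2.0, box.height * factor / 2.0
    x_min, x_max = _round_away(cx - hw), _round_away(cx + hw)
    y_min, y_max = _round_away(cy - hh), _round_away(cy + hh)
    if image_size is not None:
        w, h = image_size
        x_min, x_max = max(0, x_min), min(w, x_max)
        y_min, y_max = max(0, y_min), min(h, y_max)
    if x_min >= x_max or y_min >= y_max:
        raise ValueError("scaled bounding box has zero area")
    return BoundingBox(x_min, y_min, x_max, y_max)


def mask_bounding_box(mask: np.ndarray) -> BoundingBox:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def build_exclusion_mask(probs: ClassProbabilityStack,
                         config: RefinementConfig) -> RegionMask:
    """Threshold the class stack into a vegetation prior.

    A pixel is excluded when any non-target class clears its inclusive
    threshold (soil >= soil_thresh, sky >= sky_thresh, grass >=
    grass_thresh); the prior keeps pixels whose target_shrub probability
    clears ``target_threshold`` and that are not excluded.
    """
    excluded = (
        (probs.layer("soil") >= config.soil_thresh)
        | (probs.layer("sky") >= config.sky_thresh)
        | (probs.layer("grass") >= config.grass_thresh)
    )
    prior = (probs.layer("target_shrub") >= config.target_threshold) & ~excluded
    return RegionMask(prior.astype(np.float64), role=MaskRole.BUSH)


def morphological_cleanup(mask: RegionMask, kernel: tuple[int, int] = (3, 3),
                          iterations: int = 1) -> RegionMask:
    """Binary opening then closing with a rectangular structuring element.

    Removes isolated single pixels (opening) and fills pinholes
    (closing); ``iterations`` repeats the open/close cycle.
    """
    m = _binary(mask)
    fp = _footprint(kernel)
    for _ in range(iterations):
        m = ndimage.binary_opening(m, structure=fp)
        m = ndimage.binary_closing(m, structure=fp)
    return RegionMask(m.astype(np.float64), role=mask.role)


# ---------------------------------------------------------------------------
# stage 2 operators


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("prior mask has no contour")
    return max(contours, key=lambda c: len(c))


def _perimeter(contour: np.ndarray) -> float:
    d = np.diff(contour, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def approximate_contour(contour: np.ndarray, epsilon_fraction: float) -> np.ndarray:
    """Ramer-Douglas-Peucker simplification at tolerance eps = fraction x perimeter."""
    eps = epsilon_fraction * _perimeter(contour)
    return measure.approximate_polygon(contour, tolerance=eps)


def edge_refine(image: RasterImage, prior: RegionMask,
                config: RefinementConfig) -> RegionMask:
    """Polygon-approximate the prior boundary, guided by an edge map.

    Hysteresis edge detection runs at (canny_low, canny_high) on the
    0-255 luminance scale; the edge map is morphologically closed and
    recorded for auditing.  The prior's longest boundary contour is
    simplified by Ramer-Douglas-Peucker at tolerance
    ``epsilon_fraction x perimeter``; the filled simplified polygon is
    intersected with the dilated prior so the refinement can only trim
    or locally regularize, never leak far outside the prior.
    """
    m = _binary(prior)
    if not m.any():
        raise ValueError("prior mask is empty")
    lum255 = image.luminance() * 255.0
    edges = feature.canny(lum255, low_threshold=config.canny_low,
                          high_threshold=config.canny_high)
    fp = _footprint(config.stage2_kernel)
    for _ in range(config.stage2_iterations):
        edges = ndimage.binary_closing(edges, structure=fp)
    contour = _longest_contour(m)
    poly = approximate_contour(contour, config.epsilon_fraction)
    filled = polygon2mask(m.shape, poly)
    dilated = m
    for _ in range(max(1, config.stage2_iterations)):
        dilated = ndimage.binary_dilation(dilated, structure=fp)
    out = filled & dilated
    if not out.any():  # pathological simplification: keep the prior
        out = m
    return RegionMask(out.astype(np.float64), role=prior.role)


def cluster_refine(image: RasterImage, prior: RegionMask, config: RefinementConfig,
                   n_clusters: Optional[int] = None) -> RegionMask:
    """Retain k-means color clusters that overlap the vegetation prior.

    k-means (fixed ``random_state``) partitions the RGB vectors of the
    working region (the prior dilated by the stage-2 kernel).  A cluster
    survives iff the fraction of its pixels lying inside the prior is at
    least ``cluster_overlap_threshold``; the output is the union of the
    surviving clusters intersected with the working region.  When the
    working region holds fewer distinct colors than clusters, the unique
    colors become the clusters.
    """
    m = _binary(prior)
    if not m.any():
        raise ValueError("prior mask is empty")
    k = n_clusters if n_clusters is not None else config.n_clusters
    fp = _footprint(config.stage2_kernel)
    working = m.copy()
    for _ in range(config.stage2_iterations):
        working = ndimage.binary_dilation(working, structure=fp)
    rgb = image.rgb()[working]
    uniq = np.unique(rgb, axis=0)
    if len(uniq) <= k:
        # degenerate palette: each distinct color is its own cluster
        labels = np.zeros(len(rgb), dtype=int)
        for i, c in enumerate(uniq):
            labels[np.all(rgb == c, axis=1)] = i
        n_lab = len(uniq)
    else:
        km = KMeans(n_clusters=k, random_state=config.random_state, n_init=10)
        labels = km.fit_predict(rgb)
        n_lab = k
    inside = m[working]
    keep = np.zeros(n_lab, dtype=bool)
    for lab in range(n_lab):
        sel = labels == lab
        if sel.sum() == 0:
            continue
        keep[lab] = inside[sel].mean() >= config.cluster_overlap_threshold
    out = np.zeros(m.shape, dtype=bool)
    out[working] = keep[labels]
    return RegionMask(out.astype(np.float64), role=prior.role)


def feather_mask(mask: RegionMask, radius_px: float) -> RegionMask:
    """Soften a mask edge by Gaussian blur with sigma = radius / 2."""
    if radius_px < 0:
        raise ValueError("feather radius must be non-negative")
    if radius_px == 0:
        return mask
    w = ndimage.gaussian_filter(mask.weights, sigma=radius_px / 2.0)
    return RegionMask(np.clip(w, 0.0, 1.0), role=mask.role)


# ---------------------------------------------------------------------------
# stage 3 operators


def shadow_correct(image: RasterImage, region: RegionMask,
                   config: RefinementConfig) -> RasterImage:
    """Brighten shadowed pixels with a smooth blend.

    The shadow score is a weighted mix of Rec.601 luminance and HSV
    value, s = luminance_weight * L + (1 - luminance_weight) * V; pixels
    in the region with s < shadow_threshold are candidates.  The
    candidate indicator is Gaussian-smoothed (sigma = blend_sigma) into
    a weight field, and each pixel is blended channelwise toward
    ``min(1, brighten_factor * pixel)``.
    """
    if image.layout is ChannelLayout.GRAY:
        raise ValueError("shadow correction requires an RGB image")
    rgb = image.rgb()
    L = image.luminance()
    V = rgb.max(axis=2)
    s = config.luminance_weight * L + (1 - config.luminance_weight) * V
    cand = (s < config.shadow_threshold) & (region.weights > 0)
    if not cand.any() or config.brighten_factor == 1.0:
        return image
    w = ndimage.gaussian_filter(cand.astype(np.float64), sigma=config.blend_sigma)
    w = np.clip(w, 0.0, 1.0)[..., None]
    bright = np.minimum(1.0, config.brighten_factor * rgb)
    out = (1 - w) * rgb + w * bright
    if image.layout is ChannelLayout.RGBA:
        out = np.dstack([out, image.pixels[..., 3]])
    return RasterImage(np.clip(out, 0, 1), image.layout)


def _saturation(rgb: np.ndarray) -> np.ndarray:
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return s


def soil_color_correct(image: RasterImage, bush: RegionMask,
                       config: RefinementConfig) -> RasterImage:
    """Push soil-colored bush pixels away from the soil endmember.

    The endmember e is the mean RGB of low-saturation background pixels
    (saturation < soil_endmember_threshold; fallback: all background
    pixels).  Bush pixels within ``color_tolerance`` Euclidean RGB
    distance of e move along p - e by ``correction_strength``.
    """
    rgb = image.rgb()
    bg = bush.weights == 0
    if not bg.any():
        raise ValueError("background region is empty")
    bg_rgb = rgb[bg]
    low_sat = _saturation(bg_rgb) < config.soil_endmember_threshold
    e = bg_rgb[low_sat].mean(axis=0) if low_sat.any() else bg_rgb.mean(axis=0)
    dist = np.linalg.norm(rgb - e, axis=2)
    sel = (bush.weights > 0) & (dist < config.color_tolerance)
    out = rgb.copy()
    out[sel] = np.clip(rgb[sel] + config.correction_strength * (rgb[sel] - e), 0, 1)
    if image.layout is ChannelLayout.RGBA:
        out = np.dstack([out, image.pixels[..., 3]])
        return RasterImage(out, ChannelLayout.RGBA)
    return RasterImage(out, ChannelLayout.RGB)


def soil_suppress(image: RasterImage, bush: RegionMask,
                  config: RefinementConfig) -> RasterImage:
    """Blend the background band just outside the bush toward mid-gray.

    The band is ``suppression_radius`` dilations of the bush support
    minus the bush itself; band pixels become
    ``(1 - strength) * p + strength * 0.5``.  Bush pixels are never
    modified — the vegetation signal is the thing being protected.
    """
    if config.suppression_strength == 0 or config.suppression_radius == 0:
        return image
    support = bush.weights > 0
    band = ndimage.binary_dilation(support, iterations=config.suppression_radius) & ~support
    rgb = image.rgb().copy()
    rgb[band] = (1 - config.suppression_strength) * rgb[band] + \
        config.suppression_strength * 0.5
    if image.layout is ChannelLayout.RGBA:
        out = np.dstack([rgb, image.pixels[..., 3]])
        return RasterImage(out, ChannelLayout.RGBA)
    return RasterImage(rgb, image.layout if image.layout is ChannelLayout.RGB
                       else ChannelLayout.RGB)


# ---------------------------------------------------------------------------
# stage 4 operators


def bicubic_resize(pixels: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bicubic resample to (height, width); channels handled jointly."""
    if tuple(out_shape) == pixels.shape[:2]:
        return pixels.copy()
    out = transform.resize(pixels, out_shape + pixels.shape[2:], order=3,
                           mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


#: Pluggable upscaler registry; a learned super-resolution model can be
#: registered under its own name without touching the pipeline.
UPSCALERS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "bicubic": lambda px, f: bicubic_resize(
        px, (int(round(px.shape[0] * f)), int(round(px.shape[1] * f)))),
}
UPSCALERS["ESRGAN_x4"] = UPSCALERS["bicubic"]  # surrogate: no bundled weights


def upscale_sharpen(image: RasterImage, config: RefinementConfig) -> RasterImage:
    """Upscale by ``upscale_factor`` then apply a blended unsharp mask.

    The sharpened result, unsharp(amount, radius), is mixed with the
    plain upscale at weight ``sharpen_strength``; amount 0 or strength 0
    leaves the pure upscale.
    """
    upscaler = UPSCALERS[config.upscaler_name if config.upscaler_name in UPSCALERS
                         else "bicubic"]
    up = upscaler(image.pixels, config.upscale_factor)
    if config.unsharp_amount == 0 or config.sharpen_strength == 0:
        return RasterImage(up, image.layout)
    sigma = config.unsharp_radius
    blurred = ndimage.gaussian_filter(
        up, sigma=(sigma, sigma) + (0,) * (up.ndim - 2))
    detail = up - blurred
    if config.unsharp_threshold > 0:
        detail = np.where(np.abs(detail) >= config.unsharp_threshold, detail, 0.0)
    sharp = np.clip(up + config.unsharp_amount * detail, 0.0, 1.0)
    out = (1 - config.sharpen_strength) * up + config.sharpen_strength * sharp
    return RasterImage(np.clip(out, 0, 1), image.layout)


def center_of_mass(mask: RegionMask) -> tuple[float, float]:
    """(y, x) centroid of the mask weights."""
    w = mask.weights
    total = w.sum()
    if total <= 0:
        raise ValueError("empty mask has no center of mass")
    ys, xs = np.mgrid[: w.shape[0], : w.shape[1]]
    return float((ys * w).sum() / total), float((xs * w).sum() / total)


def _crop_window(mask: RegionMask, config: RefinementConfig,
                 image_shape: tuple[int, int]) -> BoundingBox:
    support = mask.weights > 0
    bbox = mask_bounding_box(support)
    cy, cx = center_of_mass(mask)
    w = bbox.width * (1 + 2 * config.padding_fraction)
    h = bbox.height * (1 + 2 * config.padding_fraction)
    # grow the short side to reach the target width:height ratio
    if w / h < config.aspect_ratio:
        w = h * config.aspect_ratio
    else:
        h = w / config.aspect_ratio
    w *= config.crop_scale_factor
    h *= config.crop_scale_factor
    H, W = image_shape
    x_min = max(0, _round_away(cx - w / 2))
    x_max = min(W, _round_away(cx + w / 2))
    y_min = max(0, _round_away(cy - h / 2))
    y_max = min(H, _round_away(cy + h / 2))
    x_max = max(x_max, x_min + 1)
    y_max = max(y_max, y_min + 1)
    return BoundingBox(x_min, y_min, min(x_max, W), min(y_max, H))


def crop_center(image: RasterImage, bush: RegionMask,
                config: RefinementConfig) -> tuple[RasterImage, RegionMask]:
    """Crop about the bush center of mass and standardize to canonical size.

    The window covers the bush bounding box padded by
    ``padding_fraction`` per side, adjusted to ``aspect_ratio``
    (width:height) by growing the short side, scaled by
    ``crop_scale_factor`` and clamped to the image; both image and mask
    are resampled bicubically to ``canonical_size``.
    """
    if bush.total_weight() <= 0:
        raise ValueError("cannot crop about an empty mask")
    win = _crop_window(bush, config, image.shape)
    out_w, out_h = config.canonical_size
    img_crop = image.pixels[win.y_min:win.y_max, win.x_min:win.x_max]
    msk_crop = bush.weights[win.y_min:win.y_max, win.x_min:win.x_max]
    img_out = bicubic_resize(img_crop, (out_h, out_w))
    msk_out = bicubic_resize(msk_crop, (out_h, out_w))
    return (RasterImage(img_out, image.layout),
            RegionMask(np.clip(msk_out, 0, 1), role=bush.role))


def compose_output(image: RasterImage, bush: RegionMask,
                   config: RefinementConfig) -> RasterImage:
    """Emit the RGBA deliverable: RGB passed through, alpha = feathered mask."""
    if image.shape != bush.shape:
        raise ValueError("image and mask dims are misaligned")
    alpha = feather_mask(bush, config.feather_radius_output).weights
    rgba = np.dstack([image.rgb(), np.clip(alpha, 0, 1)])
    return RasterImage(rgba, ChannelLayout.RGBA)


# ---------------------------------------------------------------------------
# full pipeline


def run_refinement(image_or_pair: RasterImage | ScenePair,
                   probs: ClassProbabilityStack,
                   config: RefinementConfig = RefinementConfig(),
                   ) -> tuple[RasterImage, RegionMask, RefinementTrace]:
    """Execute stages 1.1 through 4.3 in order.

    Accepts either a bare raster or a scene pair (in which case the
    reconstructed raster is refined).  Returns the standardized RGBA
    prior, the final vegetation mask, and a complete stage trace.  The
    run is fully deterministic for fixed inputs and config.
    """
    image = (image_or_pair.reconstructed if isinstance(image_or_pair, ScenePair)
             else image_or_pair)
    if probs.shape != image.shape:
        raise ValueError("probability stack dims must match the image")
    trace = RefinementTrace()

    def _n(mask: RegionMask) -> int:
        return int((mask.weights > 0.5).sum())

    # --- stage 1.1: binary foreground decision + scaled localization box
    fg = probs.layer("target_shrub") >= config.target_threshold
    if not fg.any():
        raise ValueError("stage 1.1: no pixel clears the target threshold")
    box = scale_box(mask_bounding_box(fg), config.box_scale_factor,
                    image_size=(image.width_px, image.height_px))
    trace.add("1.1", "scale_box", int(fg.sum()), int(fg.sum()),
              box_scale_factor=config.box_scale_factor, box=dataclasses.astuple(box))

    # --- stages 1.2-1.3: exclusion thresholds -> vegetation prior inside box
    prior = build_exclusion_mask(probs, config)
    trace.add("1.2", "class_probability_ingest", _n(prior), _n(prior),
              classes=list(probs.class_names))
    box_sel = np.zeros(image.shape, dtype=bool)
    box_sel[box.y_min:box.y_max, box.x_min:box.x_max] = True
    prior = RegionMask((prior.weights > 0) & box_sel, role=MaskRole.BUSH)
    trace.add("1.3", "build_exclusion_mask", _n(prior), _n(prior),
              soil_thresh=config.soil_thresh, sky_thresh=config.sky_thresh,
              grass_thresh=config.grass_thresh)

    # --- stage 1.4: morphological cleanup
    before = _n(prior)
    prior = morphological_cleanup(prior, config.stage1_kernel, config.stage1_iterations)
    trace.add("1.4", "morphological_cleanup", before, _n(prior),
              kernel=config.stage1_kernel, iterations=config.stage1_iterations)
    if prior.total_weight() == 0:
        raise ValueError("stage 1.4: prior vanished during cleanup")

    # --- stage 2.1: edge-guided contour simplification
    before = _n(prior)
    prior = edge_refine(image, prior, config)
    trace.add("2.1", "edge_refine", before, _n(prior),
              canny=(config.canny_low, config.canny_high),
              epsilon_fraction=config.epsilon_fraction)

    # --- stage 2.2: color-cluster retention
    before = _n(prior)
    prior = cluster_refine(image, prior, config)
    trace.add("2.2", "cluster_refine", before, _n(prior),
              n_clusters=config.n_clusters, random_state=config.random_state,
              overlap_threshold=config.cluster_overlap_threshold)

    # --- stage 2.3: feathering (graded support for the radiometric stages)
    feathered = feather_mask(prior, config.feather_radius_stage2)
    trace.add("2.3", "feather_mask", _n(prior), _n(feathered),
              feather_radius=config.feather_radius_stage2)

    # --- stage 3.1-3.3: radiometric corrections on the image
    work = image if image.layout is not ChannelLayout.GRAY else \
        RasterImage(np.repeat(image.pixels[..., None], 3, axis=2), ChannelLayout.RGB)
    work = shadow_correct(work, feathered, config)
    trace.add("3.1", "shadow_correct", _n(prior), _n(prior),
              shadow_threshold=config.shadow_threshold,
              brighten_factor=config.brighten_factor)
    work = soil_color_correct(work, prior, config)
    trace.add("3.2", "soil_color_correct", _n(prior), _n(prior),
              color_tolerance=config.color_tolerance,
              correction_strength=config.correction_strength)
    work = soil_suppress(work, prior, config)
    trace.add("3.3", "soil_suppress", _n(prior), _n(prior),
              suppression_radius=config.suppression_radius,
              strength=config.suppression_strength)

    # --- stage 3.4: second cleanup pass
    before = _n(prior)
    prior = morphological_cleanup(prior, config.stage3_kernel, config.stage3_iterations)
    trace.add("3.4", "morphological_cleanup", before, _n(prior),
              kernel=config.stage3_kernel, iterations=config.stage3_iterations)
    if prior.total_weight() == 0:
        raise ValueError("stage 3.4: prior vanished during cleanup")

    # --- stage 4.1: upscale + sharpen
    work_up = upscale_sharpen(work, config)
    mask_up = RegionMask(
        bicubic_resize(prior.weights, work_up.shape) > 0.5, role=MaskRole.BUSH)
    trace.add("4.1", "upscale_sharpen", _n(prior), _n(mask_up),
              upscale_factor=config.upscale_factor, upscaler=config.upscaler_name,
              amount=config.unsharp_amount, strength=config.sharpen_strength)

    # --- stage 4.2: center crop to canonical size
    before = _n(mask_up)
    work_std, mask_std = crop_center(work_up, mask_up, config)
    trace.add("4.2", "crop_center", before, _n(mask_std),
              canonical_size=config.canonical_size,
              scale_factor=config.crop_scale_factor)

    # --- stage 4.3: RGBA composition
    final_mask = RegionMask(mask_std.weights > 0.5, role=MaskRole.BUSH)
    out = compose_output(work_std, final_mask, config) if config.alpha_channel \
        else work_std
    trace.add("4.3", "compose_output", _n(final_mask), _n(final_mask),
              alpha_channel=config.alpha_channel,
              feather_radius=config.feather_radius_output)
    return out, final_mask, trace
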