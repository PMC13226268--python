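"""Synthetic rangeland scene-pair generator.

Emulates the structure of dryland shrub photography — a connected
target-shrub region with its own intensity distribution on a
heterogeneous soil/litter/stone/shadow background — together with a
"reconstructed" counterpart that keeps the shrub pixels bit-identical
while replacing the background with structured texture of controllable
mean and variance.  Class-probability stacks emulating a scene parser
and on-disk datasets with JSON manifests round out the fixtures.

Everything is a pure function of (preset, seed).  Generated scenes make
no claim to photorealism: they exist so the refinement and assessment
machinery can be exercised and validated against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .imaging import (
    ChannelLayout,
    ClassProbabilityStack,
    MaskRole,
    RasterImage,
    RegionMask,
    ScenePair,
    write_mask,
    write_probability_stack,
    write_raster,
)

#: Default frame (width, height): quarter of the canonical raster size,
#: chosen for desk-scale runtime; pass canonical 1184x864 for full-size scenes.
DEFAULT_SIZE = (296, 216)

BACKGROUND_KINDS = ("sandy", "rocky", "litter", "shadowed")
SHRUB_KINDS = ("sparse", "dense", "thorny")

# Rec.601-neutral chroma offsets: adding them to a luminance field yields
# an RGB image whose Rec.601 luminance equals the field exactly.
_BUSH_CHROMA = np.array([-0.05, (0.299 * 0.05 + 0.114 * 0.05) / 0.587, -0.05])
_BG_CHROMA = np.array([0.05, -(0.299 * 0.05 - 0.114 * 0.03) / 0.587, -0.03])

# luminance clamp keeping tint addition clip-free
_L_LO, _L_HI = 0.06, 0.94

_TARGET_AREA_FRACTION = {"sparse": 0.10, "dense": 0.25, "thorny": 0.16}
_SHADOW_FACTOR = 0.3  # multiplicative attenuation inside shadow patches


@dataclass(frozen=True)
class ScenePreset:
    """Controls one synthetic original/reconstructed scene pair.

    The luminance moments are the targets of the respective region
    textures before kind-specific artifacts (stones, litter speckle,
    shadow patches) are layered on; the sandy background carries no
    artifacts, so its empirical moments match the preset directly.
    """

    background_kind: str = "sandy"
    shrub_kind: str = "sparse"
    bush_mean: float = 0.55
    bush_std: float = 0.06
    bg_mean_orig: float = 0.40
    bg_std_orig: float = 0.05
    bg_mean_recon: float = 0.40
    bg_std_recon: float = 0.11
    shadow_fraction: float = 0.15
    image_size: tuple[int, int] = DEFAULT_SIZE  # (width, height)
    seed: int = 0

    def __post_init__(self):
        if self.background_kind not in BACKGROUND_KINDS:
            raise ValueError(f"unknown background kind {self.background_kind!r}")
        if self.shrub_kind not in SHRUB_KINDS:
            raise ValueError(f"unknown shrub kind {self.shrub_kind!r}")
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ValueError("shadow_fraction must lie in [0, 1]")
        for name in ("bush_mean", "bg_mean_orig", "bg_mean_recon"):
            if not _L_LO <= getattr(self, name) <= _L_HI:
                raise ValueError(f"{name} must lie in [{_L_LO}, {_L_HI}]")


@dataclass(frozen=True)
class ManifestRow:
    pair_id: str
    class_label: str
    preset: ScenePreset
    original_path: str
    reconstructed_path: str
    bush_mask_path: str
    class_probs_path: str


@dataclass(frozen=True)
class DatasetManifest:
    root: Path
    rows: tuple[ManifestRow, ...]
    manifest_path: Path


# ---------------------------------------------------------------------------
# mask generation


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             axes: tuple[float, float], angle: float) -> np.ndarray:
    H, W = shape
    ys, xs = np.mgrid[:H, :W]
    dy, dx = ys - center[0], xs - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def generate_shrub_mask(preset: ScenePreset, seed: Optional[int] = None) -> RegionMask:
    """A connected binary shrub blob covering 5-40% of the frame.

    An elliptical core; dense and thorny kinds add branch-like random
    protrusions.  The result is forced to a single 4-connected
    component and its area fraction kept within [0.05, 0.40].
    """
    rng = np.random.default_rng(preset.seed if seed is None else seed)
    W, H = preset.image_size
    shape = (H, W)
    frac = _TARGET_AREA_FRACTION[preset.shrub_kind]
    ratio = rng.uniform(1.0, 1.6)
    # pi*a*b = frac*H*W with a/b = ratio
    b = np.sqrt(frac * H * W / (np.pi * ratio))
    a = ratio * b
    cy = H / 2 + rng.uniform(-0.08, 0.08) * H
    cx = W / 2 + rng.uniform(-0.08, 0.08) * W
    mask = _ellipse(shape, (cy, cx), (a, b), rng.uniform(0, np.pi))
    if preset.shrub_kind in ("dense", "thorny"):
        n_branch = 8 if preset.shrub_kind == "thorny" else 5
        for _ in range(n_branch):
            ang = rng.uniform(0, 2 * np.pi)
            # branch: a small elongated ellipse rooted on the core boundary
            ry, rx = cy + 0.8 * a * np.sin(ang), cx + 0.8 * b * np.cos(ang)
            blen = rng.uniform(0.15, 0.35) * min(a, b) + 3
            mask |= _ellipse(shape, (ry, rx), (blen, max(2.0, blen / 4)), ang)
    mask &= np.ones(shape, dtype=bool)  # clip to frame implicitly via grid
    labels, n = ndimage.label(mask, structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    if n > 1:  # keep the largest 4-connected component
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    lo, hi = 0.05 * H * W, 0.40 * H * W
    while mask.sum() < lo:
        mask = ndimage.binary_dilation(mask)
    while mask.sum() > hi:
        mask = ndimage.binary_erosion(mask)
    return RegionMask(mask.astype(np.float64), role=MaskRole.BUSH)


# ---------------------------------------------------------------------------
# texture fields (luminance domain)


def _gaussian_field(rng: np.random.Generator, shape, mean, std) -> np.ndarray:
    return rng.normal(mean, std, shape)


def _structured_field(rng: np.random.Generator, shape, mean, std) -> np.ndarray:
    """Smoothed multi-scale noise plus periodic patches, standardized to
    the requested moments: the 'restructured' background of a
    reconstructed scene."""
    H, W = shape
    f = ndimage.gaussian_filter(rng.normal(0, 1, shape), 2.0)
    f += 0.6 * ndimage.gaussian_filter(rng.normal(0, 1, shape), 8.0)
    ys, xs = np.mgrid[:H, :W]
    lam = rng.uniform(18, 40)
    f += 0.4 * np.sin(2 * np.pi * xs / lam + rng.uniform(0, 2 * np.pi)) \
        * np.sin(2 * np.pi * ys / (lam * rng.uniform(0.7, 1.4))
                 + rng.uniform(0, 2 * np.pi))
    f = (f - f.mean()) / f.std()
    return mean + std * f


def _apply_background_artifacts(field: np.ndarray, kind: str, shadow_fraction: float,
                                rng: np.random.Generator) -> np.ndarray:
    H, W = field.shape
    out = field.copy()
    if kind == "rocky":
        for _ in range(6):  # low-frequency bright stone blobs
            c = (rng.uniform(0, H), rng.uniform(0, W))
            ax = (rng.uniform(4, 12), rng.uniform(4, 12))
            out[_ellipse(field.shape, c, ax, rng.uniform(0, np.pi))] += \
                rng.uniform(0.1, 0.25)
    elif kind == "litter":
        speckle = rng.random(field.shape) < 0.02
        speckle = ndimage.binary_dilation(speckle, iterations=1)
        out[speckle] += rng.choice([-0.15, 0.2], size=int(speckle.sum()))
    elif kind == "shadowed" and shadow_fraction > 0:
        covered = np.zeros(field.shape, dtype=bool)
        target = shadow_fraction * H * W
        for _ in range(50):
            if covered.sum() >= target:
                break
            c = (rng.uniform(0, H), rng.uniform(0, W))
            ax = (rng.uniform(8, H / 4), rng.uniform(8, W / 4))
            covered |= _ellipse(field.shape, c, ax, rng.uniform(0, np.pi))
        out[covered] *= _SHADOW_FACTOR
    return out


def _tint(lum: np.ndarray, bush: np.ndarray, ) -> np.ndarray:
    """Lift a luminance field to RGB with region chroma whose Rec.601
    luminance equals the field exactly (greenish bush, brownish background)."""
    L = np.clip(lum, _L_LO, _L_HI)
    rgb = np.empty(L.shape + (3,))
    chroma = np.where(bush[..., None], _BUSH_CHROMA, _BG_CHROMA)
    rgb[:] = L[..., None] + chroma
    return np.clip(rgb, 0.0, 1.0)


def generate_scene_pair(preset: ScenePreset) -> ScenePair:
    """One original/reconstructed pair with bit-identical shrub pixels.

    The original background is Gaussian texture (plus kind-specific
    artifacts); the reconstructed background is a structured field at
    the preset's reconstructed moments.  The bush texture is drawn once
    and pasted into both rasters.
    """
    rng = np.random.default_rng(preset.seed)
    W, H = preset.image_size
    shape = (H, W)
    mask = generate_shrub_mask(preset, seed=preset.seed)
    m = mask.weights > 0

    bush_lum = _gaussian_field(rng, shape, preset.bush_mean, preset.bush_std)
    bg_orig = _gaussian_field(rng, shape, preset.bg_mean_orig, preset.bg_std_orig)
    bg_orig = _apply_background_artifacts(bg_orig, preset.background_kind,
                                          preset.shadow_fraction, rng)
    bg_recon = _structured_field(rng, shape, preset.bg_mean_recon, preset.bg_std_recon)

    lum_orig = np.where(m, bush_lum, bg_orig)
    lum_recon = np.where(m, bush_lum, bg_recon)
    orig = RasterImage(_tint(lum_orig, m), ChannelLayout.RGB)
    recon_px = _tint(lum_recon, m)
    recon_px[m] = orig.pixels[m]  # bush pixels bit-identical by construction
    recon = RasterImage(recon_px, ChannelLayout.RGB)
    return ScenePair(original=orig, reconstructed=recon, bush_mask=mask,
                     pair_id=f"synthetic-{preset.seed}",
                     class_label=preset.shrub_kind)


# ---------------------------------------------------------------------------
# class probabilities


_INSIDE_PROBS = {"soil": 0.06, "sky": 0.01, "grass": 0.03, "target_shrub": 0.90}
_OUTSIDE_PROBS = {
    "sandy": {"soil": 0.90, "sky": 0.03, "grass": 0.05, "target_shrub": 0.02},
    "rocky": {"soil": 0.88, "sky": 0.05, "grass": 0.05, "target_shrub": 0.02},
    "litter": {"soil": 0.78, "sky": 0.02, "grass": 0.18, "target_shrub": 0.02},
    "shadowed": {"soil": 0.85, "sky": 0.08, "grass": 0.05, "target_shrub": 0.02},
}


def generate_class_probabilities(pair: ScenePair, noise_level: float = 0.0,
                                 seed: int = 0, background_kind: str = "sandy",
                                 ) -> ClassProbabilityStack:
    """A scene-parser surrogate: high target_shrub probability inside the
    mask (0.9 at zero noise), background-kind-appropriate class mix
    outside; symmetric noise is added and the stack renormalized."""
    if not 0.0 <= noise_level <= 0.5:
        raise ValueError("noise_level must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    m = pair.bush_mask.weights > 0
    H, W = pair.original.shape
    probs = np.empty((H, W, 4))
    inside = np.array([_INSIDE_PROBS[c] for c in ("soil", "sky", "grass", "target_shrub")])
    outside = np.array([_OUTSIDE_PROBS[background_kind][c]
                        for c in ("soil", "sky", "grass", "target_shrub")])
    probs[:] = np.where(m[..., None], inside, outside)
    if noise_level > 0:
        probs = probs + rng.uniform(-noise_level, noise_level, probs.shape)
        probs = np.clip(probs, 1e-6, None)
    probs = probs / probs.sum(axis=2, keepdims=True)
    return ClassProbabilityStack(probs)


# ---------------------------------------------------------------------------
# datasets


def _derive_presets(n_pairs: int, class_specs: Sequence, seed: int,
                    ) -> list[tuple[str, ScenePreset]]:
    labels = []
    for spec in class_specs:
        label = spec if isinstance(spec, str) else spec[0]
        if label in labels:
            raise ValueError(f"duplicate class label {label!r}")
        labels.append(label)
    base = {spec if isinstance(spec, str) else spec[0]:
            ({} if isinstance(spec, str) else dict(spec[1])) for spec in class_specs}
    out = []
    for i in range(n_pairs):
        label = labels[i % len(labels)]
        overrides = dict(base[label])
        overrides.setdefault("background_kind",
                             BACKGROUND_KINDS[i % len(BACKGROUND_KINDS)])
        overrides.setdefault("shrub_kind", SHRUB_KINDS[i % len(SHRUB_KINDS)])
        out.append((label, ScenePreset(seed=seed + i, **overrides)))
    return out


def generate_pair_set(n_pairs: int, class_specs: Sequence, seed: int,
                      ) -> list[ScenePair]:
    """In-memory dataset: scene pairs with deterministic per-pair seeds
    (master seed + pair index) cycled over the class specs."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    pairs = []
    for i, (label, preset) in enumerate(_derive_presets(n_pairs, class_specs, seed)):
        pair = generate_scene_pair(preset)
        pairs.append(replace(pair, pair_id=f"pair-{i:04d}", class_label=label))
    return pairs


def generate_dataset(n_pairs: int, class_specs: Sequence, seed: int,
                     out_dir: str | Path, probs_noise: float = 0.05,
                     ) -> DatasetManifest:
    """Write a full on-disk dataset: PNG images and masks, 16-bit
    multi-page TIFF probability stacks, and a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    presets = _derive_presets(n_pairs, class_specs, seed)
    for i, (label, preset) in enumerate(presets):
        pair = generate_scene_pair(preset)
        pid = f"pair-{i:04d}"
        probs = generate_class_probabilities(pair, probs_noise, seed=preset.seed,
                                             background_kind=preset.background_kind)
        paths = {
            "original_path": f"{pid}_original.png",
            "reconstructed_path": f"{pid}_reconstructed.png",
            "bush_mask_path": f"{pid}_mask.png",
            "class_probs_path": f"{pid}_probs.tif",
        }
        write_raster(pair.original, out_dir / paths["original_path"])
        write_raster(pair.reconstructed, out_dir / paths["reconstructed_path"])
        write_mask(pair.bush_mask, out_dir / paths["bush_mask_path"])
        write_probability_stack(probs, out_dir / paths["class_probs_path"])
        rows.append(ManifestRow(pair_id=pid, class_label=label, preset=preset,
                                **paths))
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps([
        {"pair_id": r.pair_id, "class_label": r.class_label,
         "original_path": r.original_path,
         "reconstructed_path": r.reconstructed_path,
         "bush_mask_path": r.bush_mask_path,
         "class_probs_path": r.class_probs_path,
         "preset": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in r.preset.__dict__.items()}}
        for r in rows], indent=2, sort_keys=True) + "\n")
    return DatasetManifest(root=out_dir, rows=tuple(rows), manifest_path=manifest_path)
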