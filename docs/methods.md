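# Methods

## Scope and data model

`shrubshift` operates on *scene pairs*: an original rangeland
photograph and a reconstructed counterpart that share one binary (or
feathered) target-shrub mask.  How the reconstruction is produced is
outside the package — generative image-to-image models, manual
compositing, or the synthetic generator shipped here all yield the same
pairing of two rasters.  Likewise the per-pixel class probabilities
consumed by the refinement pipeline are an ingestion contract
(`ClassProbabilityStack`, ordered classes soil/sky/grass/target_shrub,
per-pixel sum 1 within 1e-6); any semantic-segmentation backbone can
produce them.

Intensities live on a normalized real [0, 1] scale internally whatever
the file bit depth; 8-bit and 16-bit files are rescaled on read and
re-quantized (round half up) on write, so a read/write round trip is
bounded by one quantization step.  Coordinates are 0-based, half-open,
row-major (y, x).  RGBA alpha is a validity channel: alpha-0 pixels are
excluded from all region statistics, so standardized RGBA outputs can
be re-assessed without the transparent surround contaminating the
background region.  Graded (feathered) masks contribute
weight-proportional statistics; binary masks are the 0/1 special case
and the default, since assessment-time masks are typically hard.

## The refinement pipeline

The pipeline is a fixed sequence of deterministic operators in four
stages; every parameter sits in one frozen `RefinementConfig`
dataclass, and the single stochastic step (k-means) takes an explicit
seed (default 42), so the whole run is a pure function of (inputs,
config) and repeated runs are bit-identical.

**Stage 1 — scene-parsing thresholds.**  A binary foreground decision
thresholds the target_shrub probability at 0.6; the bounding box of the
result is scaled about its center by 0.8 (round half away from zero,
clamp to the frame) to localize the working area.  An exclusion mask is
the union of soil ≥ 0.7, sky ≥ 0.8 and grass ≥ 0.6; the vegetation
prior is the thresholded foreground minus the exclusion, intersected
with the scaled box.  All comparators are inclusive (≥) so boundary
pixels behave identically across platforms.  A (3,3) binary
opening-then-closing removes isolated pixels and pinholes.

**Stage 2 — boundary refinement.**  Canny edges at thresholds (50, 150)
are computed on the 0–255 luminance scale — the conventional scale for
those printed values even though the package works in [0, 1] — and the
edge map is closed ((3,3), 2 iterations) and recorded in the trace for
auditing.  The prior's longest boundary contour is simplified by
Ramer–Douglas–Peucker at tolerance 0.01 × perimeter, filled, and
intersected with the dilated prior, so simplification can regularize
the boundary but never leak far outside it.  k-means (k = 5, seed 42)
then partitions the RGB vectors of the dilated prior; a cluster
survives iff at least 10 % of its pixels lie inside the prior.  When
the region holds fewer distinct colors than clusters, the unique colors
become the clusters (deterministic fallback).  Feathering is Gaussian
blur of the mask with σ = radius/2 (radius 3 px here, 2 px at output);
radius 0 is an exact identity.

**Stage 3 — radiometric cleanup.**  The shadow score is
s = 0.7·L + 0.3·V (L Rec.601 luminance, V = max(R,G,B)); pixels with
s < 0.3 inside the working region are candidates, their indicator is
Gaussian-smoothed (σ = 2) into a blend weight, and each pixel moves
toward min(1, 1.3·p).  A brighten factor of 1 is an exact identity.
Soil color correction estimates a soil endmember as the mean RGB of
low-saturation (< 0.2) background pixels and pushes bush pixels within
RGB distance 0.1 of it away along p − e by strength 0.5.  Soil
suppression blends a 3-px band just outside the bush toward mid-gray at
strength 0.8; bush pixels are never modified — the preservation of the
vegetation signal is a hard contract, tested bit-exactly.  A second
(3,3) cleanup pass follows.

**Stage 4 — standardization.**  The image is upscaled ×4 (bicubic; the
upscaler is a registry, so a learned super-resolution model can be
plugged in under its own name — none is bundled) and sharpened by an
unsharp mask (amount 1.2, radius 0.5, threshold 0) blended at weight
0.6.  The crop window sits at the mask's center of mass, covers its
bounding box padded 10 % per side, is grown on the short side to
width:height = 1.1, scaled ×1.5 and clamped; image and mask are
resampled bicubically to the canonical 1184 × 864 output.  The
deliverable is RGBA with alpha = the 2-px-feathered mask.

Where only an operator *name* and its parameters are fixed by
convention, the package commits to one concrete member of the implied
family (the shadow score as a luminance/value mix, soil suppression as
blend-to-gray in a boundary band, aspect ratio read as width:height to
match the landscape canonical frame, the stage-2 retention threshold
read as a cluster-overlap fraction).  Each choice is documented at the
operator and pluggable via the config; none affects the assessment
half.

## Assessment metrics

All metrics default to Rec.601 luminance of RGB inputs (a per-channel
mean option exists).  Histograms use R = 256 equal-width bins on
[0, 1], matching an 8-bit reading of "intensity value i"; σ is the
population (weight-normalized) standard deviation, treating the region
as the full population of its pixels.  CoV is undefined at μ = 0 and
raises rather than returning a sentinel.  Rao's Q uses
d_ij = |bin-center difference| on the normalized axis, so Q ≤ 1.

The Bhattacharyya distance defaults to the univariate-Gaussian closed
form on region (μ, σ); a nonparametric histogram estimator
(−ln Σ √(pᵢqᵢ)) is provided as an alternative since the parametric
assumption is a modeling choice, not a theorem.  JM = 2(1 − e^{−B}) is
strictly increasing and bounded: mathematically JM < 2 always, but once
B exceeds ≈ 37, e^{−B} drops below the resolution of a double next to
1 and the computed value saturates at exactly 2.0 — tests assert strict
monotonicity only where the exponential is float-resolvable.  The
"excellent" grade cutpoint (JM > 1.9) is the standard remote-sensing
convention; the lower cutpoints (1.7, 1.0) are package conventions and
are flagged as such in output metadata.

Per-pair shifts are Δ = 100·(recon − orig)/orig; relative change is not
antisymmetric under swapping the pair (+100 % maps to −50 %), which is
documented behavior.  Aggregation takes the arithmetic mean of per-pair
shifts within each class, and the Global row pools over *pairs*, not
over class means; the estimator is a documented choice (the alternative
— relative shift of group means — is not what a per-pair design
implies).  Deltas whose original metric is zero are undefined: they are
excluded from means, counted in a diagnostics field, and warned about.

## The synthetic generator

Presets name the background condition (sandy, rocky, litter, shadowed)
and canopy form (sparse, dense, thorny) of a scene.  The shrub mask is
an elliptical core (plus branch-like protrusions for dense/thorny
kinds) forced to a single 4-connected component occupying 5–40 % of the
frame.  The original background is Gaussian texture at the preset's
(μ, σ); rocky adds low-frequency bright blobs, litter adds
salt-and-pepper clusters, shadowed multiplies elliptical patches by
0.3.  The reconstructed background is smoothed multi-scale noise plus a
periodic component, standardized exactly to the preset's reconstructed
moments — by default more variable (σ 0.11 vs 0.05 at mean 0.40) so the
background CoV and entropy shifts come out positive, qualitatively
mirroring the texture-redistribution signature of generative
reconstruction without claiming any real-data magnitudes.  Bush pixels
are drawn once and pasted into both rasters, so bush-pixel preservation
is bit-exact by construction.

RGB is produced by adding fixed Rec.601-null chroma offsets (greenish
for bush, brownish for background) to the luminance field, so the
luminance statistics of the generated scene equal the prescribed
moments exactly; the field is clamped to [0.06, 0.94] before tinting,
which is beyond 6σ of every default and therefore negligible for
moment-recovery checks.  The parser surrogate assigns target_shrub
probability 0.9 inside the mask and a background-kind-appropriate mix
outside, adds symmetric uniform noise and renormalizes.

Default frame size is 296 × 216 (a quarter of the canonical size per
axis), a desk-scale choice that keeps a full test run under half a
minute; the canonical 1184 × 864 is available by preset.  Per-pair
seeds are master seed + pair index, stable across platforms.

What passing tests on synthetic scenes shows — and what it does not:
the metrics recover prescribed moments and separability within
sampling error, the pipeline recovers the generator's ground-truth
mask on easy scenes, and all bookkeeping (per-class counts, pooled
means, determinism) is exact.  Synthetic backgrounds are far simpler
than real rangeland imagery (no perspective, no real plant morphology,
no correlated illumination), so none of this certifies real-data shift
magnitudes.

## Numerical choices and degenerate inputs

- Geometric rounding is half-away-from-zero, then clamp; a scaled box
  that collapses to zero area raises, while one that survives rounding
  as a single pixel is returned as the minimal box.
- Histogram proportions must sum to 1 within 1e-9; 0·ln 0 := 0.
- Empty regions, empty priors, zero-variance regions, and GRAY input to
  RGB-only operators raise `ValueError` with named messages rather than
  propagating NaNs.
- Empty k-means clusters are dropped; morphological cleanup of an
  entirely isolated-pixel mask may legitimately empty it, which the
  pipeline reports as a stage-annotated error.
- The neutral-parameter configuration (scale factors 1, strengths 0,
  amounts 0, radii 0, iterations 0, tolerance 0) reduces the pipeline
  to thresholding plus an identity crop; this is verified against a
  hand-built oracle on a 16×16 stack.

## Validation problem sizes

Moment-recovery checks run at ~10⁵ background pixels (3-standard-error
bands via the delta-method SE of the CoV); the separability-recovery
check uses 100 seeded replicates at 96 × 72 px with a ≥ 6σ bush/
background mean gap, requiring JM > 1.9 in at least 99 of them; the
bookkeeping check aggregates 98 pairs over 10 classes at 96 × 72 px.
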