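# shrubshift

Vegetation-prior refinement and paired spectral-domain shift assessment
for rangeland scene imagery.

## The problem

Monitoring shrubs in arid rangelands from RGB photographs is hard
because exposed soil, dry litter, stones and shadows share intensity
statistics with the target vegetation.  One workflow family deals with
this by pairing each raw field image with a *reconstructed* counterpart
in which the background has been replaced by simpler, restructured
texture while the target-shrub pixels are preserved, then deriving an
annotation-ready vegetation prior from the pair.  Two questions follow:

1. **Refinement** — given a raw or reconstructed image plus per-pixel
   class probabilities (soil / sky / grass / target_shrub) from any
   scene parser, how do you deterministically turn them into a clean,
   standardized target-shrub mask?
2. **Assessment** — what did the reconstruction actually do to the
   scene's spectral statistics, region by region?

`shrubshift` implements both halves for researchers in ecological
computer vision: a fully parameterized, bit-reproducible four-stage
refinement pipeline, and a paired assessment framework built on four
masked-region metrics, computed on Rec.601 luminance:

- coefficient of variation `CoV = 100·σ/μ` (relative texture),
- Shannon entropy `H′ = −Σᵢ pᵢ ln pᵢ` over `R` intensity bins (tonal
  complexity),
- Rao's quadratic entropy `Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ` with `dᵢⱼ` the bin-center
  distance on the normalized intensity axis (abundance-weighted
  spectral divergence),
- Jeffries–Matusita separability `JM = 2(1 − e^{−B})` between the bush
  and background (Bg) regions, where `B` is the Bhattacharyya distance;
  `JM ∈ [0, 2)` and values above 1.9 conventionally read as excellent
  separability.

For each original/reconstructed pair the percent shift
`Δ = 100·(reconstructed − original)/original` of `CoV_Bg`, `H′_Bg`,
`CoV_Bush` and `JM` is recorded, then aggregated per class and globally
into a shift table.

Because real paired field imagery is rarely redistributable, the
package includes a seeded synthetic scene-pair generator (shrub blob +
textured background + structured reconstructed background, with exact
ground truth) so that every stage can be exercised and validated.

## Worked example

`python examples/assess_scene_pair.py` generates one synthetic sandy
scene pair whose reconstructed background is deliberately more variable
than the original, and prints:

```
pair synthetic-7  (296x216 px)
  bush/original      mean=0.549 CoV= 10.97% H'=4.148 nats  Q=0.0679
  bg/original        mean=0.400 CoV= 12.49% H'=3.967 nats  Q=0.0564
  bg/reconstructed   mean=0.401 CoV= 27.54% H'=4.755 nats  Q=0.1255
  JM original      1.199
  JM reconstructed 0.703
  shifts: dCoV_Bg_pct=+120.5%  dH_Bg_pct=+19.9%  dCoV_Bush_pct=+0.0%  dJM_pct=-41.4%
```

The background CoV roughly doubles (+120.5 %) and its entropy rises
(+19.9 %) — texture redistribution, not smoothing — while the bush CoV
shift is exactly zero because the generator preserves bush pixels
bit-identically.  `examples/refine_vegetation_prior.py` runs the
refinement pipeline on the same kind of scene and reports an
intersection-over-union of 0.819 against the generator's ground-truth
mask; `examples/build_shift_table.py` prints a per-class + Global shift
table in the one-decimal, explicit-sign CSV format.

A thin CLI wraps the same functions:

```
shrubshift simulate --n-pairs 10 --seed 1 --out ds/
shrubshift assess --manifest ds/manifest.json --out report/
shrubshift refine --image img.png --probs probs.tif --out-dir out/
shrubshift report --seed 1 --out run/        # simulate + assess in one go
```

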