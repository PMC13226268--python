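"""Unit checks of the individual refinement-stage operators."""

import numpy as np
import pytest

from shrubshift.imaging import (
    BoundingBox,
    ChannelLayout,
    ClassProbabilityStack,
    MaskRole,
    RasterImage,
    RegionMask,
)
from shrubshift.refine import (
    RefinementConfig,
    build_exclusion_mask,
    cluster_refine,
    compose_output,
    crop_center,
    edge_refine,
    feather_mask,
    center_of_mass,
    morphological_cleanup,
    scale_box,
    shadow_correct,
    soil_color_correct,
    soil_suppress,
    upscale_sharpen,
)

CFG = RefinementConfig()


def _probs(soil, sky, grass, shrub, shape=(1, 1)):
    p = np.zeros(shape + (4,))
    p[..., 0], p[..., 1], p[..., 2], p[..., 3] = soil, sky, grass, shrub
    return ClassProbabilityStack(p)


class TestScaleBox:
    def test_identity_factor(self):
        box = BoundingBox(0, 0, 100, 100)
        assert scale_box(box, 1.0) == box

    def test_shrink_about_center(self):
        assert scale_box(BoundingBox(0, 0, 100, 100), 0.8) == BoundingBox(10, 10, 90, 90)

    def test_tiny_factor_leaves_minimal_one_pixel_box(self):
        assert scale_box(BoundingBox(0, 0, 3, 3), 0.1) == BoundingBox(1, 1, 2, 2)

    def test_degenerate_result_raises(self):
        # half-extent below the rounding step collapses the box entirely
        with pytest.raises(ValueError):
            scale_box(BoundingBox(0, 0, 2, 2), 0.01)


class TestExclusionMask:
    def test_soil_dominated_pixel_excluded(self):
        prior = build_exclusion_mask(_probs(0.9, 0.0, 0.0, 0.1), CFG)
        assert prior.weights[0, 0] == 0

    def test_pure_target_pixel_kept(self):
        prior = build_exclusion_mask(_probs(0.0, 0.0, 0.0, 1.0), CFG)
        assert prior.weights[0, 0] == 1

    def test_threshold_comparator_is_inclusive(self):
        # soil exactly at its threshold: excluded even with high shrub prob
        p = np.zeros((2, 2, 4))
        p[..., 0], p[..., 3] = 0.2, 0.8
        p[0, 0, 0], p[0, 0, 3] = 0.7, 0.3
        p[0, 0] /= p[0, 0].sum()  # keep the soil value exactly 0.7
        p[0, 0] *= 1.0
        stack = ClassProbabilityStack(p)
        prior = build_exclusion_mask(stack, CFG)
        assert prior.weights[0, 0] == 0
        assert prior.weights[1, 1] == 1


class TestMorphologicalCleanup:
    def test_empty_mask_stays_empty(self):
        out = morphological_cleanup(RegionMask(np.zeros((8, 8))))
        assert out.total_weight() == 0

    def test_solid_block_preserved(self):
        m = np.zeros((16, 16))
        m[3:13, 3:13] = 1
        out = morphological_cleanup(RegionMask(m), (3, 3), 1)
        # oracle: erosion then dilation of a solid block with a full
        # rectangular footprint restores it; closing cannot grow it
        assert np.array_equal(out.weights, m)

    def test_single_pixel_removed_by_opening(self):
        m = np.zeros((9, 9))
        m[4, 4] = 1
        out = morphological_cleanup(RegionMask(m), (3, 3), 1)
        assert out.total_weight() == 0

    def test_rejects_graded_mask(self):
        with pytest.raises(ValueError):
            morphological_cleanup(RegionMask(np.full((4, 4), 0.5)))


class TestEdgeRefine:
    def test_square_prior_on_uniform_image_is_exact(self, uniform_rgb, square_prior):
        out = edge_refine(uniform_rgb, square_prior, CFG)
        assert np.array_equal(out.weights, square_prior.weights)

    def test_square_contour_simplifies_to_four_vertices(self, square_prior):
        from shrubshift.refine import _longest_contour, approximate_contour

        poly = approximate_contour(_longest_contour(square_prior.weights > 0), 0.01)
        uniq = poly[:-1] if np.allclose(poly[0], poly[-1]) else poly
        assert len(uniq) == 4

    def test_disk_area_preserved_within_5_percent(self):
        from skimage.draw import disk

        m = np.zeros((100, 100))
        rr, cc = disk((50, 50), 30)
        m[rr, cc] = 1
        img = RasterImage(np.full((100, 100, 3), 0.5), ChannelLayout.RGB)
        out = edge_refine(img, RegionMask(m, role=MaskRole.BUSH), CFG)
        assert abs(out.total_weight() - m.sum()) / m.sum() < 0.05

    def test_empty_prior_raises(self, uniform_rgb):
        with pytest.raises(ValueError):
            edge_refine(uniform_rgb, RegionMask(np.zeros((40, 40))), CFG)


class TestClusterRefine:
    def test_two_color_oracle(self, square_prior):
        # pure green inside the prior, pure brown outside; with k = 2 the
        # exhaustive assignment retains the green cluster (overlap 1.0)
        # and drops the brown one (overlap < 0.1)
        px = np.zeros((40, 40, 3))
        px[...] = (0.5, 0.3, 0.1)  # brown
        inside = square_prior.weights > 0
        px[inside] = (0.1, 0.8, 0.1)  # green
        img = RasterImage(px, ChannelLayout.RGB)
        out = cluster_refine(img, square_prior, CFG, n_clusters=2)
        assert np.array_equal(out.weights > 0, inside)

    def test_uniform_color_keeps_working_region(self, uniform_rgb, square_prior):
        out = cluster_refine(uniform_rgb, square_prior, CFG)
        # single effective cluster fully retained -> output = working region
        from scipy import ndimage

        working = square_prior.weights > 0
        for _ in range(CFG.stage2_iterations):
            working = ndimage.binary_dilation(working, structure=np.ones((3, 3), bool))
        assert np.array_equal(out.weights > 0, working)

    def test_fixed_seed_is_deterministic(self, square_prior):
        rng = np.random.default_rng(3)
        img = RasterImage(rng.random((40, 40, 3)), ChannelLayout.RGB)
        a = cluster_refine(img, square_prior, CFG)
        b = cluster_refine(img, square_prior, CFG)
        assert np.array_equal(a.weights, b.weights)


class TestFeatherMask:
    def test_radius_zero_is_identity(self, square_prior):
        assert feather_mask(square_prior, 0.0) is square_prior

    def test_all_ones_invariant_under_blur(self):
        m = RegionMask(np.ones((16, 16)))
        assert np.allclose(feather_mask(m, 5.0).weights, 1.0)

    def test_step_edge_softens_symmetrically_about_half(self):
        step = np.zeros((21, 41))
        step[:, 20:] = 1.0
        f = feather_mask(RegionMask(step), 3.0).weights
        # discrete Gaussian step response: the two pixels flanking the
        # former edge bracket 0.5 and sum to 1
        assert f[10, 19] < 0.5 < f[10, 20]
        assert f[10, 19] + f[10, 20] == pytest.approx(1.0, abs=1e-9)

    def test_negative_radius_rejected(self, square_prior):
        with pytest.raises(ValueError):
            feather_mask(square_prior, -1.0)


class TestShadowCorrect:
    def test_no_candidates_is_identity(self, uniform_rgb, square_prior):
        out = shadow_correct(uniform_rgb, square_prior, CFG)
        assert np.array_equal(out.pixels, uniform_rgb.pixels)

    def test_isolated_dark_core_brightened_by_factor(self):
        # before blending, the corrected core value is brighten_factor * p
        px = np.full((41, 41, 3), 0.9)
        px[20, 20] = 0.2
        region = RegionMask(np.ones((41, 41)))
        cfg = RefinementConfig(blend_sigma=1e-6)  # no spatial blending
        out = shadow_correct(RasterImage(px, ChannelLayout.RGB), region, cfg)
        assert out.pixels[20, 20, 0] == pytest.approx(1.3 * 0.2)

    def test_unit_brighten_factor_is_identity(self, square_prior):
        px = np.full((40, 40, 3), 0.1)  # everything shadowed
        cfg = RefinementConfig(brighten_factor=1.0)
        out = shadow_correct(RasterImage(px, ChannelLayout.RGB), square_prior, cfg)
        assert np.array_equal(out.pixels, px)

    def test_gray_input_rejected(self, square_prior):
        with pytest.raises(ValueError):
            shadow_correct(RasterImage(np.zeros((40, 40)), ChannelLayout.GRAY),
                           square_prior, CFG)


class TestSoilCorrection:
    def _scene(self):
        # background: flat low-saturation sand; bush square in the middle
        px = np.full((40, 40, 3), 0.5)
        m = np.zeros((40, 40))
        m[10:30, 10:30] = 1
        return px, RegionMask(m, role=MaskRole.BUSH)

    def test_pixel_at_endmember_is_fixed_point(self):
        px, bush = self._scene()
        out = soil_color_correct(RasterImage(px, ChannelLayout.RGB), bush, CFG)
        assert np.array_equal(out.pixels, px)

    def test_nearby_pixel_pushed_away_along_same_direction(self):
        px, bush = self._scene()
        px[15, 15] = (0.55, 0.5, 0.5)  # distance 0.05 from endmember
        out = soil_color_correct(RasterImage(px, ChannelLayout.RGB), bush, CFG)
        moved = out.pixels[15, 15]
        assert np.allclose(moved, (0.575, 0.5, 0.5))  # 0.05 * 1.5 along +R

    def test_distant_bush_pixels_unchanged(self):
        px, bush = self._scene()
        px[bush.weights > 0] = (0.1, 0.8, 0.1)  # far from the soil endmember
        out = soil_color_correct(RasterImage(px, ChannelLayout.RGB), bush, CFG)
        assert np.array_equal(out.pixels, px)

    def test_suppression_band_blends_to_gray(self):
        px, bush = self._scene()
        px[...] = 1.0
        out = soil_suppress(RasterImage(px, ChannelLayout.RGB), bush, CFG)
        # band pixel just outside the bush: 0.2 * 1 + 0.8 * 0.5 = 0.6
        assert out.pixels[9, 15, 0] == pytest.approx(0.6)
        # far-field background untouched
        assert out.pixels[0, 0, 0] == 1.0

    def test_bush_pixels_never_modified_by_suppression(self):
        px, bush = self._scene()
        rng = np.random.default_rng(1)
        px = rng.random((40, 40, 3))
        out = soil_suppress(RasterImage(px, ChannelLayout.RGB), bush, CFG)
        inside = bush.weights > 0
        assert np.array_equal(out.pixels[inside], px[inside])

    def test_zero_strength_is_identity(self):
        px, bush = self._scene()
        cfg = RefinementConfig(suppression_strength=0.0)
        img = RasterImage(px, ChannelLayout.RGB)
        assert soil_suppress(img, bush, cfg) is img


class TestUpscaleAndStandardize:
    def test_constant_image_stays_constant_at_4x(self):
        img = RasterImage(np.full((10, 10, 3), 0.42), ChannelLayout.RGB)
        out = upscale_sharpen(img, CFG)
        assert out.shape == (40, 40)
        assert np.allclose(out.pixels, 0.42)

    def test_zero_amount_equals_plain_bicubic(self):
        # a smooth band-limited field, where resampling-grid conventions
        # of independent bicubic implementations agree away from borders
        ys, xs = np.mgrid[:10, :12]
        smooth = 0.5 + 0.35 * np.sin(xs / 4.0) * np.cos(ys / 3.0)
        img = RasterImage(np.repeat(smooth[..., None], 3, axis=2), ChannelLayout.RGB)
        cfg = RefinementConfig(unsharp_amount=0.0)
        out = upscale_sharpen(img, cfg)
        from PIL import Image

        ref = np.asarray(
            Image.fromarray((smooth * 255).astype(np.uint8))
            .resize((48, 40), Image.BICUBIC)) / 255.0
        assert np.abs(out.pixels[6:-6, 6:-6, 0] - ref[6:-6, 6:-6]).max() < 0.02

    def test_center_of_mass_of_single_pixel(self):
        m = np.zeros((30, 30))
        m[20, 10] = 1
        assert center_of_mass(RegionMask(m)) == (20.0, 10.0)

    def test_crop_output_dims_always_canonical(self, sandy_pair):
        out, mask = crop_center(sandy_pair.original, sandy_pair.bush_mask, CFG)
        assert out.shape == (864, 1184)  # canonical (width 1184, height 864)
        assert mask.shape == (864, 1184)

    def test_compose_output_alpha_contract(self, uniform_rgb, square_prior):
        out = compose_output(uniform_rgb, square_prior, CFG)
        alpha = out.pixels[..., 3]
        assert out.layout is ChannelLayout.RGBA
        assert alpha.min() >= 0 and alpha.max() <= 1
        # feathering makes boundary alpha strictly fractional
        assert 0 < alpha[10, 9] < 1 or 0 < alpha[9, 10] < 1
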