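"""Otsu selection, Gaussian smoothing, morphology, contours and the cascade."""

import numpy as np
import pytest

from wbcseg import (
    BinaryMask,
    ChannelImage,
    ParameterError,
    RasterImage,
    SegmentationConfig,
    SemanticError,
    SmearSceneConfig,
    apply_threshold,
    dice_coefficient,
    draw_contours,
    extract_contours,
    gaussian_filter,
    generate_scene,
    morphological_open,
    otsu_threshold,
    triple_threshold_segment,
)


def brute_force_otsu(values):
    """Exhaustive 256-candidate maximizer of w0*w1*(mu0-mu1)^2, smallest-t ties.

    Evaluates the criterion in exact rational arithmetic so that exact ties
    (which occur even on random integer images) break deterministically
    toward the smallest threshold.
    """
    from fractions import Fraction

    v = [int(x) for x in np.rint(np.asarray(values, dtype=float)).ravel()]
    n = len(v)
    best_t, best_var = 0, Fraction(0)
    for t in range(256):
        lo = [x for x in v if x <= t]
        hi = [x for x in v if x > t]
        if not lo or not hi:
            continue
        w0 = Fraction(len(lo), n)
        w1 = Fraction(len(hi), n)
        d = Fraction(sum(lo), len(lo)) - Fraction(sum(hi), len(hi))
        var = w0 * w1 * d * d
        if var > best_var:
            best_t, best_var = t, var
    return best_t, float(best_var)


class TestGaussianFilter:
    def test_constant_preserved(self):
        ch = ChannelImage(np.full((6, 8), 77.0))
        out = gaussian_filter(ch, 5, 1.1)
        np.testing.assert_allclose(out.pixels, 77.0, atol=1e-9)

    def test_impulse_matches_direct_convolution(self):
        impulse = np.zeros((9, 9))
        impulse[4, 4] = 1.0
        out = gaussian_filter(ChannelImage(impulse), 3, 0.8)
        x = np.arange(-1, 2, dtype=float)
        k1 = np.exp(-(x**2) / (2 * 0.8**2))
        k1 /= k1.sum()
        kernel2d = np.outer(k1, k1)
        np.testing.assert_allclose(out.pixels[3:6, 3:6], kernel2d, atol=1e-12)
        assert out.pixels.sum() == pytest.approx(1.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_filter(ChannelImage(np.zeros((4, 4))), 4, 1.0)

    def test_shape_preserved(self, rng):
        ch = ChannelImage(rng.uniform(0, 255, (11, 7)))
        assert gaussian_filter(ch, 5, 1.1).shape == (11, 7)


class TestOtsu:
    def test_perfectly_bimodal_ties_to_smallest(self):
        res = otsu_threshold(np.array([0, 0, 255, 255]))
        assert res.threshold == 0
        assert res.between_class_variance == pytest.approx(127.5**2)

    def test_matches_brute_force_on_worked_example(self):
        values = np.array([10, 10, 10, 10, 200, 200, 200, 90])
        res = otsu_threshold(values)
        t, var = brute_force_otsu(values)
        assert res.threshold == t
        assert res.between_class_variance == pytest.approx(var)

    def test_constant_image_degrades_gracefully(self):
        res = otsu_threshold(ChannelImage(np.full((3, 3), 128.0)))
        assert res.threshold == 128
        assert res.between_class_variance == 0.0

    def test_histogram_sums_to_pixel_count(self, rng):
        arr = rng.integers(0, 256, size=(13, 17))
        res = otsu_threshold(ChannelImage(arr.astype(float)))
        assert res.histogram.sum() == arr.size

    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(10):
            arr = rng.integers(0, 256, size=(12, 12))
            res = otsu_threshold(ChannelImage(arr.astype(float)))
            t, var = brute_force_otsu(arr)
            assert res.threshold == t
            assert res.between_class_variance == pytest.approx(var)

    def test_agrees_with_skimage_on_bimodal_image(self, rng):
        """Independent library cross-check on a well-separated mixture."""
        from skimage.filters import threshold_otsu

        arr = np.concatenate(
            [rng.normal(60, 8, 600), rng.normal(190, 8, 400)]
        ).clip(0, 255)
        ours = otsu_threshold(arr).threshold
        theirs = threshold_otsu(np.rint(arr).astype(np.uint8), nbins=256)
        assert abs(ours - int(theirs)) <= 1  # binning conventions differ by <= 1

    def test_variance_decomposition_identity(self, rng):
        """sigma_b^2(t) + sigma_w^2(t) == total variance at every threshold."""
        v = np.rint(rng.uniform(0, 255, 500))
        total = v.var()
        n = v.size
        for t in range(0, 256, 17):
            lo, hi = v[v <= t], v[v > t]
            w0, w1 = lo.size / n, hi.size / n
            sb = w0 * w1 * (lo.mean() - hi.mean()) ** 2 if lo.size and hi.size else 0.0
            sw = w0 * (lo.var() if lo.size else 0.0) + w1 * (hi.var() if hi.size else 0.0)
            assert sb + sw == pytest.approx(total, abs=1e-9 * max(1.0, total))


class TestApplyThreshold:
    def test_boundary_pixel_excluded_above(self):
        ch = ChannelImage(np.array([[0.0, 100.0, 200.0]]))
        assert apply_threshold(ch, 100, "above").pixels.tolist() == [[0, 0, 1]]

    def test_below_is_complement(self):
        ch = ChannelImage(np.array([[0.0, 100.0, 200.0]]))
        assert apply_threshold(ch, 100, "below").pixels.tolist() == [[1, 1, 0]]

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ParameterError):
            apply_threshold(ChannelImage(np.zeros((2, 2))), 300, "above")


class TestMorphologicalOpen:
    def test_element_sized_square_is_invariant(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[3:16, 3:16] = 1
        out = morphological_open(BinaryMask(mask), 13, 1)
        np.testing.assert_array_equal(out.pixels, mask)

    def test_sub_element_object_removed(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[8:13, 8:13] = 1
        out = morphological_open(BinaryMask(mask), 13, 1)
        assert out.foreground_count == 0

    def test_idempotent_and_anti_extensive_on_random_masks(self, rng):
        for _ in range(20):
            mask = BinaryMask((rng.uniform(size=(16, 16)) < 0.45).astype(np.uint8))
            once = morphological_open(mask, 3, 1)
            twice = morphological_open(once, 3, 1)
            assert twice == once  # idempotence
            assert np.all(once.bool <= mask.bool)  # anti-extensive

    def test_staged_vs_repeated_modes(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[5:30, 5:30] = 1
        staged = morphological_open(BinaryMask(mask), 5, 2, mode="staged")
        repeated = morphological_open(BinaryMask(mask), 5, 2, mode="repeated")
        # repeated = plain opening (idempotent); both anti-extensive
        np.testing.assert_array_equal(
            repeated.pixels, morphological_open(BinaryMask(mask), 5, 1).pixels
        )
        assert np.all(staged.bool <= mask.astype(bool))

    def test_invalid_parameters_rejected(self):
        m = BinaryMask(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ParameterError):
            morphological_open(m, 0, 1)
        with pytest.raises(ParameterError):
            morphological_open(m, 3, 0)


class TestContours:
    def test_empty_mask_gives_empty_set(self):
        cs = extract_contours(BinaryMask(np.zeros((5, 5), dtype=np.uint8)))
        assert len(cs) == 0

    def test_solid_square_single_contour_encloses_it(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:6, 3:7] = 1
        cs = extract_contours(BinaryMask(mask))
        assert len(cs) == 1
        verts = {tuple(v) for v in cs.contours[0]}
        expected_boundary = {
            (r, c)
            for r in range(2, 6)
            for c in range(3, 7)
            if r in (2, 5) or c in (3, 6)
        }
        assert verts == expected_boundary

    def test_two_components_two_contours(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        mask[7:11, 7:11] = 1
        assert len(extract_contours(BinaryMask(mask))) == 2

    def test_single_pixel_degenerates_to_repeated_vertex(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        cs = extract_contours(BinaryMask(mask))
        assert len(cs) == 1
        assert {tuple(v) for v in cs.contours[0]} == {(2, 2)}

    def test_vertices_stay_in_bounds_for_border_object(self):
        mask = np.ones((4, 6), dtype=np.uint8)
        cs = extract_contours(BinaryMask(mask))
        poly = cs.contours[0]
        assert poly[:, 0].min() >= 0 and poly[:, 0].max() < 4
        assert poly[:, 1].min() >= 0 and poly[:, 1].max() < 6


class TestDrawContours:
    def _image(self):
        return RasterImage(np.full((10, 10, 3), 50, dtype=np.uint8))

    def test_empty_contour_set_is_noop(self):
        from wbcseg import ContourSet

        img = self._image()
        out = draw_contours(img, ContourSet([], (10, 10)), (0, 255, 0))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_exactly_boundary_pixels_change(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:6, 3:7] = 1
        cs = extract_contours(BinaryMask(mask))
        img = self._image()
        out = draw_contours(img, cs, (0, 255, 0))
        changed = np.argwhere(np.any(out.pixels != img.pixels, axis=2))
        boundary = {tuple(v) for v in cs.contours[0]}
        assert {tuple(p) for p in changed} == boundary
        np.testing.assert_array_equal(img.pixels, 50)  # input untouched

    def test_shape_mismatch_rejected(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:3, 1:3] = 1
        cs = extract_contours(BinaryMask(mask))
        with pytest.raises(SemanticError):
            draw_contours(self._image(), cs, (255, 0, 0))


class TestTripleThreshold:
    def test_default_scene_recovered(self, default_scene):
        mask = triple_threshold_segment(default_scene.image)
        assert dice_coefficient(mask, default_scene.wbc_mask) >= 0.90

    def test_blank_white_field_gives_empty_mask(self):
        blank = RasterImage(np.full((64, 64, 3), 255, dtype=np.uint8))
        assert triple_threshold_segment(blank).foreground_count == 0

    def test_rbc_only_scene_nearly_empty(self):
        scene = generate_scene(SmearSceneConfig(seed=3, n_wbc=0))
        mask = triple_threshold_segment(scene.image)
        assert mask.foreground_count / mask.pixels.size < 0.01

    def test_deterministic(self, default_scene):
        a = triple_threshold_segment(default_scene.image)
        b = triple_threshold_segment(default_scene.image)
        assert a == b

    def test_non_rgb_rejected(self):
        gray = RasterImage(np.zeros((8, 8, 1), dtype=np.uint8), "GRAY")
        with pytest.raises(SemanticError):
            triple_threshold_segment(gray)

    def test_intermediates_one_record_per_pass(self, default_scene):
        cfg = SegmentationConfig()
        mask, records = triple_threshold_segment(
            default_scene.image, cfg, return_intermediates=True
        )
        assert len(records) == cfg.n_passes
        assert [r.round_index for r in records] == [1, 2, 3]
        # surviving sets shrink monotonically across rounds
        prev = np.ones(mask.shape, dtype=bool)
        for rec in records:
            assert np.all(rec.mask.bool <= prev)
            prev = rec.mask.bool

    def test_config_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SegmentationConfig(gaussian_kernel=7, n_passes=2)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SegmentationConfig.from_yaml(str(path)) == cfg

    def test_config_unknown_key_rejected(self):
        with pytest.raises(ParameterError, match="bogus"):
            SegmentationConfig.from_dict({"bogus": 1})
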