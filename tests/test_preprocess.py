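"""Preprocessing stages: text masking, Retinex, ROI, rotation, resize."""

import numpy as np
import pytest

from fundusfusion.phantom import text_band
from fundusfusion.preprocess import (
    PreprocessConfig,
    ROISpec,
    RetinexParams,
    apply_roi,
    augment_rotate,
    default_config_for,
    mask_text,
    preprocess_pipeline,
    resize_image,
    retinex,
    roi_mask,
    rotate_ccw,
)


def _gradient_image(h=60, w=90):
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    base = 60 + 120 * np.abs(np.sin(rr / 9) * np.cos(cc / 13))
    return np.stack([base, 0.8 * base, 0.5 * base], axis=-1)


class TestMaskText:
    def test_band_zeroed_others_untouched(self, tiny_image, tiny_spec):
        band = text_band(tiny_spec)
        out = mask_text(tiny_image, band)
        r0, r1, c0, c1 = band
        assert np.all(out[r0:r1, c0:c1] == 0)
        outside = out.copy()
        outside[r0:r1, c0:c1] = tiny_image[r0:r1, c0:c1]
        np.testing.assert_array_equal(outside, tiny_image.astype(float))

    def test_empty_band_is_identity(self, tiny_image):
        np.testing.assert_array_equal(
            mask_text(tiny_image, (0, 0, 0, 0)), tiny_image.astype(float)
        )

    def test_whole_image_band_blacks_out(self, tiny_image):
        h, w = tiny_image.shape[:2]
        assert np.all(mask_text(tiny_image, (0, h, 0, w)) == 0)

    def test_out_of_bounds_band_rejected(self, tiny_image):
        h, w = tiny_image.shape[:2]
        with pytest.raises(ValueError):
            mask_text(tiny_image, (0, h + 1, 0, w))


class TestRetinex:
    def test_uniform_image_maps_to_constant(self):
        img = np.full((40, 50, 3), 120.0)
        out = retinex(img, RetinexParams(surround_sigma=5.0))
        for ch in range(3):
            assert np.ptp(out[..., ch]) < 1e-9

    def test_invariance_to_smooth_multiplicative_gain(self):
        img = _gradient_image(120, 180)
        cc = np.arange(img.shape[1], dtype=float)
        # relative gain slope ~0.1/180 per px, far slower than sigma=8
        gain = 1.0 + 0.1 * (cc / img.shape[1] - 0.5)
        params = RetinexParams(surround_sigma=8.0)
        plain = retinex(img, params) / 255.0
        gained = retinex(img * gain[None, :, None], params) / 255.0
        assert np.max(np.abs(plain - gained)) < 1e-2

    def test_flattens_phantom_illumination_gradient(self):
        h, w = 80, 120
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        detail = 80 + 60 * np.sin(rr / 4) * np.cos(cc / 5)
        grad = 1.0 + 0.5 * (cc / w - 0.5)  # left/right halves differ > 20%
        img = np.stack([detail * grad] * 3, axis=-1)
        left_in, right_in = img[:, : w // 2].mean(), img[:, w // 2 :].mean()
        assert abs(left_in - right_in) / max(left_in, right_in) > 0.2
        out = retinex(img, RetinexParams(surround_sigma=10.0))
        left, right = out[:, : w // 2].mean(), out[:, w // 2 :].mean()
        assert abs(left - right) / max(left, right) < 0.05

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            RetinexParams(surround_sigma=0.0)


class TestApplyRoi:
    ROI = ROISpec(center_row=30, center_col=45, semi_axis_row=15,
                  semi_axis_col=20, outside_treatment="black_fill")

    def test_outside_pixels_zero_inside_kept(self, tiny_image):
        roi = ROISpec(30, 45, 15, 20, "black_fill")
        out = apply_roi(tiny_image, roi)
        mask = roi_mask(tiny_image.shape[:2], roi)
        assert np.all(out[~mask] == 0)
        np.testing.assert_array_equal(out[mask], tiny_image.astype(float)[mask])

    def test_whole_image_roi_black_fill_is_identity(self, tiny_image):
        h, w = tiny_image.shape[:2]
        roi = ROISpec(h / 2, w / 2, 10 * h, 10 * w, "black_fill")
        np.testing.assert_array_equal(apply_roi(tiny_image, roi), tiny_image.astype(float))

    def test_mass_conservation_vs_bruteforce(self, tiny_image):
        roi = self.ROI
        out = apply_roi(tiny_image, roi)
        total = 0.0
        img = tiny_image.astype(float)
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                if ((r - roi.center_row) / roi.semi_axis_row) ** 2 + (
                    (c - roi.center_col) / roi.semi_axis_col
                ) ** 2 <= 1.0:
                    total += img[r, c].sum()
        assert out.sum() == pytest.approx(total)

    def test_delete_crops_to_bounding_box(self, tiny_image):
        roi = ROISpec(30, 45, 15, 20, "delete")
        out = apply_roi(tiny_image, roi)
        assert out.shape[0] <= 2 * 15 + 2 and out.shape[1] <= 2 * 20 + 2
        filled = apply_roi(tiny_image, ROISpec(30, 45, 15, 20, "black_fill"))
        assert out.sum() == pytest.approx(filled.sum())

    def test_idempotent_black_fill(self, tiny_image):
        roi = self.ROI
        once = apply_roi(tiny_image, roi)
        twice = apply_roi(once, roi)
        np.testing.assert_array_equal(once, twice)

    def test_disjoint_roi_rejected(self, tiny_image):
        with pytest.raises(ValueError):
            apply_roi(tiny_image, ROISpec(-500, -500, 5, 5, "black_fill"))


class TestRotation:
    def test_angle_drawn_from_allowed_set(self, tiny_image):
        seen = set()
        for seed in range(30):
            _, _, angle = augment_rotate(tiny_image, np.random.default_rng(seed))
            seen.add(angle)
        assert seen <= {30, 60, 90, 120, 180}
        assert len(seen) >= 3

    def test_90_degrees_preserves_pixel_multiset(self):
        rng = np.random.default_rng(0)
        square = rng.integers(0, 255, (40, 40, 3)).astype(float)
        rot = rotate_ccw(square, 90)
        assert sorted(square.ravel()) == sorted(rot.ravel())

    def test_180_twice_is_identity(self, tiny_image):
        back = rotate_ccw(rotate_ccw(tiny_image, 180), 180)
        np.testing.assert_array_equal(back, tiny_image.astype(float))

    def test_returns_original_unchanged(self, tiny_image, rng):
        original, rotated, angle = augment_rotate(tiny_image, rng)
        np.testing.assert_array_equal(original, tiny_image.astype(float))
        assert angle in {30, 60, 90, 120, 180}


class TestResize:
    def test_target_shape_from_500x750(self):
        img = np.random.default_rng(1).random((500, 750, 3)) * 255
        out = resize_image(img)
        assert out.shape == (78, 116, 3)

    def test_constant_image_stays_constant(self):
        img = np.full((100, 130, 3), 77.0)
        out = resize_image(img, (13, 29))
        np.testing.assert_allclose(out, 77.0, rtol=1e-9)

    def test_checkerboard_mean_preserved(self):
        tile = np.array([[0.0, 255.0], [255.0, 0.0]])
        board = np.tile(tile, (50, 75))
        img = np.stack([board] * 3, axis=-1)
        out = resize_image(img)
        assert out.mean() == pytest.approx(img.mean(), rel=0.01)

    def test_mean_preserved_on_random_image(self, tiny_image):
        out = resize_image(tiny_image)
        assert out.mean() == pytest.approx(tiny_image.astype(float).mean(), rel=0.01)

    def test_degenerate_target_rejected(self, tiny_image):
        with pytest.raises(ValueError):
            resize_image(tiny_image, (0, 10))


class TestPipeline:
    def test_two_outputs_of_fixed_shape(self, tiny_image, tiny_spec):
        config = default_config_for(tiny_spec.image_rows, tiny_spec.image_cols,
                                    band=text_band(tiny_spec))
        out = preprocess_pipeline(tiny_image, config, rng=5, source_id="S0")
        assert len(out) == 2
        for proc in out:
            assert proc.pixels.shape == (78, 116, 3)
            assert np.all(np.isfinite(proc.pixels))
        assert out[0].rotation_deg == 0
        assert out[1].rotation_deg in {30, 60, 90, 120, 180}

    def test_deterministic_under_seed(self, tiny_image, tiny_spec):
        config = default_config_for(tiny_spec.image_rows, tiny_spec.image_cols)
        a = preprocess_pipeline(tiny_image, config, rng=5)
        b = preprocess_pipeline(tiny_image, config, rng=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.pixels, pb.pixels)
            assert pa.rotation_deg == pb.rotation_deg

    def test_shape_invariant_to_input_size(self):
        config = default_config_for(97, 143)
        img = np.random.default_rng(2).random((97, 143, 3)) * 255
        out = preprocess_pipeline(img, config, rng=1)
        assert all(p.pixels.shape == (78, 116, 3) for p in out)
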