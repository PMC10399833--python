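"""Canonicalization geometry: background, alignment, scale, crop."""

import math

import numpy as np
import pytest

from cleftscore.fixtures import FixtureSpec, make_face
from cleftscore.imaging import ImageGrid, LandmarkSet
from cleftscore.preprocess import (FaceBox, GeometryError,
                                   LandmarkTruthBackend, PreprocessConfig,
                                   adjust_background, align_eyes,
                                   blur_background, crop_canonical,
                                   mirror_canvas, preprocess_face,
                                   scale_to_interocular)


def _landmarks_with_eyes(right_rc, left_rc, frame=200):
    pts = np.full((68, 2), frame / 2.0)
    pts[36:42] = right_rc
    pts[42:48] = left_rc
    return LandmarkSet(pts)


class TestAdjustBackground:
    def test_already_at_target_is_a_no_op(self):
        rng = np.random.default_rng(0)
        img = ImageGrid(rng.uniform(0, 1, (100, 100, 3)))
        side = int(round(math.sqrt(0.6) * 100))  # ~60% face fraction
        box = FaceBox(10, 10, side, side)
        out, out_box = adjust_background(img, box, 0.6)
        assert out is img and out_box is box

    def test_oversized_face_gets_mirrored_margin(self):
        rng = np.random.default_rng(1)
        img = ImageGrid(rng.uniform(0, 1, (100, 100, 3)))
        box = FaceBox(5, 5, 90, 90)  # fraction 0.81
        out, out_box = adjust_background(img, box, 0.6)
        assert out.height > 100 and out.width > 100
        frac = out_box.area / (out.height * out.width)
        assert 0.55 <= frac <= 0.65

    def test_undersized_face_gets_margin_cropped(self):
        rng = np.random.default_rng(2)
        img = ImageGrid(rng.uniform(0, 1, (100, 100, 3)))
        box = FaceBox(40, 40, 30, 30)  # fraction 0.09
        out, out_box = adjust_background(img, box, 0.6)
        assert out.height < 100 and out.width < 100
        frac = out_box.area / (out.height * out.width)
        assert 0.55 <= frac <= 0.65

    def test_mirror_margin_reflects_border_pixels(self):
        rng = np.random.default_rng(3)
        img = ImageGrid(rng.uniform(0, 1, (10, 8, 3)))
        big = mirror_canvas(img)
        assert big.shape == (30, 24, 3)
        # pixel just above the original top edge equals the top row itself
        np.testing.assert_array_equal(big.pixels[9, 8:16], img.pixels[0])
        np.testing.assert_array_equal(big.pixels[10:20, 7], img.pixels[:, 0])

    def test_degenerate_box_rejected(self):
        img = ImageGrid(np.zeros((10, 10, 3)))
        with pytest.raises(GeometryError, match="positive"):
            adjust_background(img, FaceBox(0, 0, 0, 5), 0.6)
        with pytest.raises(GeometryError, match="degenerate"):
            adjust_background(img, FaceBox(0, 0, 1, 1), 0.6)


class TestBlurBackground:
    def test_constant_image_unchanged(self):
        img = ImageGrid(np.full((40, 40, 3), 0.3))
        out = blur_background(img, FaceBox(10, 10, 20, 20), sigma=3.0)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_whole_image_box_is_identity(self):
        rng = np.random.default_rng(4)
        img = ImageGrid(rng.uniform(0, 1, (30, 30, 3)))
        out = blur_background(img, FaceBox(0, 0, 30, 30), sigma=2.0)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-9)

    def test_background_smoothed_foreground_preserved(self):
        checker = np.indices((60, 60)).sum(axis=0) % 2
        img = ImageGrid(np.repeat(checker[:, :, None], 3, axis=2).astype(float))
        box = FaceBox(20, 20, 20, 20)
        out = blur_background(img, box, sigma=3.0)
        # face-box interior essentially untouched
        inner = slice(21, 39)
        assert np.abs(out.pixels[inner, inner] -
                      img.pixels[inner, inner]).max() < 1.0 / 255.0
        # background variance strictly decreases
        bg = np.s_[45:, 45:]
        assert out.pixels[bg].var() < img.pixels[bg].var()


class TestAlignEyes:
    def test_horizontal_eyes_are_a_no_op(self):
        rng = np.random.default_rng(5)
        img = ImageGrid(rng.uniform(0, 1, (200, 200, 3)))
        lm = _landmarks_with_eyes([100.0, 80.0], [100.0, 120.0])
        out, out_lm, angle = align_eyes(img, lm)
        assert angle == 0.0
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_tilted_eyes_become_horizontal(self):
        rng = np.random.default_rng(6)
        img = ImageGrid(rng.uniform(0, 1, (200, 200, 3)))
        lm = _landmarks_with_eyes([100.0, 100.0], [50.0, 150.0])
        out, out_lm, angle = align_eyes(img, lm)
        dr = out_lm.left_eye_center[0] - out_lm.right_eye_center[0]
        assert abs(dr) < 0.5
        # rotation preserves the interocular distance
        assert out_lm.interocular_distance == pytest.approx(
            lm.interocular_distance, rel=1e-9)

    def test_aligning_twice_is_idempotent(self):
        rng = np.random.default_rng(7)
        img = ImageGrid(rng.uniform(0, 1, (200, 200, 3)))
        lm = _landmarks_with_eyes([100.0, 100.0], [80.0, 150.0])
        out, out_lm, angle1 = align_eyes(img, lm)
        _, _, angle2 = align_eyes(out, out_lm)
        assert abs(angle2) < 0.01

    def test_coincident_eyes_rejected(self):
        img = ImageGrid(np.zeros((50, 50, 3)))
        lm = _landmarks_with_eyes([25.0, 25.0], [25.0, 25.0], frame=50)
        with pytest.raises(GeometryError, match="coincident"):
            align_eyes(img, lm)


class TestScaleToInterocular:
    @pytest.mark.parametrize("distance,expected_scale", [
        (100.0, 1.0), (50.0, 2.0), (200.0, 0.5)])
    def test_scale_factor_from_eye_distance(self, distance, expected_scale):
        rng = np.random.default_rng(8)
        img = ImageGrid(rng.uniform(0, 1, (300, 300, 3)))
        lm = _landmarks_with_eyes([150.0, 150.0 - distance / 2],
                                  [150.0, 150.0 + distance / 2], frame=300)
        out, out_lm, s = scale_to_interocular(img, lm, target_distance=100.0)
        assert s == pytest.approx(expected_scale)
        assert out_lm.interocular_distance == pytest.approx(100.0, abs=0.5)

    def test_zero_distance_rejected(self):
        img = ImageGrid(np.zeros((50, 50, 3)))
        lm = _landmarks_with_eyes([25.0, 25.0], [25.0, 25.0], frame=50)
        with pytest.raises(GeometryError, match="zero"):
            scale_to_interocular(img, lm, 100.0)


class TestCropCanonical:
    def test_identity_when_window_matches_frame(self):
        rng = np.random.default_rng(9)
        img = ImageGrid(rng.uniform(0, 1, (8, 8, 3)))
        pts = np.full((68, 2), 4.0)
        pts[36:42] = [4 - 0.08 * 8, 2.0]
        pts[42:48] = [4 - 0.08 * 8, 6.0]
        out, _, origin = crop_canonical(img, LandmarkSet(pts), side=8)
        assert origin == (0, 0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_crop_center_matches_index_arithmetic(self):
        rng = np.random.default_rng(10)
        img = ImageGrid(rng.uniform(0, 1, (300, 300, 3)))
        lm = _landmarks_with_eyes([120.0, 130.0], [120.0, 170.0], frame=300)
        side = 100
        out, out_lm, origin = crop_canonical(img, lm, side=side,
                                             v_offset_frac=0.1)
        r0 = int(round(120.0 + 0.1 * side - side / 2))
        c0 = int(round(150.0 - side / 2))
        assert origin == (r0, c0)
        assert out.shape == (side, side, 3)
        np.testing.assert_array_equal(out.pixels,
                                      img.pixels[r0:r0 + side, c0:c0 + side])
        # the anchor ends up within 1 px of the crop center
        anchor = out_lm.eye_midpoint + [0.1 * side, 0]
        np.testing.assert_allclose(anchor, [side / 2, side / 2], atol=1.0)

    def test_overrunning_window_reflect_pads(self):
        rng = np.random.default_rng(11)
        img = ImageGrid(rng.uniform(0, 1, (60, 60, 3)))
        lm = _landmarks_with_eyes([10.0, 20.0], [10.0, 40.0], frame=60)
        out, _, _ = crop_canonical(img, lm, side=60, v_offset_frac=0.08)
        assert out.shape == (60, 60, 3)


class TestFullPreprocess:
    def test_canonical_geometry_at_toy_scale(self):
        img, lm = make_face(FixtureSpec(seed=1))
        cfg = PreprocessConfig(face_fraction=0.6, eye_distance=20.0, side=64)
        canon, canon_lm, meta = preprocess_face(img, LandmarkTruthBackend(lm),
                                                cfg)
        assert canon.shape == (64, 64, 3)
        assert canon_lm.interocular_distance == pytest.approx(20.0, abs=0.5)
        dr = canon_lm.left_eye_center[0] - canon_lm.right_eye_center[0]
        assert abs(dr) < 0.5

    def test_idempotent_up_to_interpolation(self):
        img, lm = make_face(FixtureSpec(seed=0, image_side=256,
                                        eye_distance=64.0))
        cfg = PreprocessConfig()  # production-scale 1024 frame
        canon1, lm1, _ = preprocess_face(img, LandmarkTruthBackend(lm), cfg)
        canon2, lm2, _ = preprocess_face(canon1, LandmarkTruthBackend(lm1),
                                         cfg)
        assert canon2.shape == canon1.shape
        assert np.abs(canon2.pixels - canon1.pixels).max() <= 2.0 / 255.0
        np.testing.assert_allclose(lm2.points, lm1.points, atol=1.0)
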