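"""Color transform, difference heatmaps, and erosion against brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cleftscore.fixtures import FixtureSpec, graded_faces
from cleftscore.heatmaps import (Heatmap, erode, perceptual_map, pse_map,
                                 rgb_to_ycbcr, ssim_map)
from cleftscore.imaging import ImageGrid, convert_range
from cleftscore.scoring import build_mask


class TestYCbCr:
    def test_black_maps_to_offsets(self):
        img = ImageGrid(np.zeros((2, 2, 3)), range_tag="unit")
        out = rgb_to_ycbcr(img)
        assert out.colorspace == "YCbCr" and out.range_tag == "byte"
        np.testing.assert_allclose(out.pixels[0, 0], [16.0, 128.0, 128.0])

    def test_white_luma_hits_nominal_peak(self):
        img = ImageGrid(np.ones((1, 1, 3)), range_tag="unit")
        y = rgb_to_ycbcr(img).pixels[0, 0, 0]
        assert y == pytest.approx(16 + 65.481 + 128.553 + 24.966, abs=1e-9)

    def test_achromatic_ramp_has_flat_chroma(self):
        ramp = np.repeat(np.linspace(0, 1, 64)[:, None], 3, axis=1)
        img = ImageGrid(np.tile(ramp[None], (4, 1, 1)), range_tag="unit")
        out = rgb_to_ycbcr(img)
        np.testing.assert_allclose(out.pixels[:, :, 1], 128.0, atol=1e-6)
        np.testing.assert_allclose(out.pixels[:, :, 2], 128.0, atol=1e-6)

    def test_byte_input_handled_via_range_conversion(self):
        byte = ImageGrid(np.full((2, 2, 3), 255.0), range_tag="byte")
        unit = ImageGrid(np.ones((2, 2, 3)), range_tag="unit")
        np.testing.assert_allclose(rgb_to_ycbcr(byte).pixels,
                                   rgb_to_ycbcr(unit).pixels)

    def test_non_rgb_rejected(self):
        ycc = rgb_to_ycbcr(ImageGrid(np.zeros((2, 2, 3))))
        with pytest.raises(ValueError, match="RGB"):
            rgb_to_ycbcr(ycc)


class TestPSE:
    def test_identical_images_give_zero_map(self):
        x = ImageGrid(np.random.default_rng(0).uniform(0, 1, (8, 8, 3)))
        assert np.all(pse_map(x, x).values == 0)

    def test_single_differing_pixel_squares_the_difference(self):
        a = np.zeros((4, 4, 3))
        b = a.copy()
        b[1, 2, 0] = 0.25
        heat = pse_map(ImageGrid(a), ImageGrid(b))
        assert heat.values[1, 2] == pytest.approx(0.25 ** 2)
        assert np.count_nonzero(heat.values) == 1

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (6, 5, 3))
        b = rng.uniform(0, 1, (6, 5, 3))
        heat = pse_map(ImageGrid(a), ImageGrid(b))
        for i in range(6):
            for j in range(5):
                want = sum((a[i, j, c] - b[i, j, c]) ** 2 for c in range(3))
                assert heat.values[i, j] == pytest.approx(want, rel=1e-12)

    def test_luma_only_channel_selection(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (4, 4, 3))
        b = rng.uniform(0, 1, (4, 4, 3))
        heat = pse_map(ImageGrid(a), ImageGrid(b), channels="first")
        np.testing.assert_allclose(heat.values, (a[:, :, 0] - b[:, :, 0]) ** 2)

    def test_colorspace_mismatch_is_contract_error(self):
        x = ImageGrid(np.zeros((4, 4, 3)))
        y = rgb_to_ycbcr(x)
        with pytest.raises(ValueError, match="mismatch"):
            pse_map(x, convert_range(y, "unit"))


class TestSSIM:
    def test_identical_images_give_zero_dissimilarity(self):
        x = ImageGrid(np.random.default_rng(0).uniform(0, 1, (16, 16, 3)))
        heat = ssim_map(x, x)
        np.testing.assert_allclose(heat.values, 0.0, atol=1e-12)

    def test_luminance_shift_matches_windowed_statistics(self):
        """A constant offset on a textured patch must reproduce the direct
        evaluation of the similarity formula from local window moments."""
        rng = np.random.default_rng(5)
        a = rng.uniform(0.2, 0.8, (15, 15, 1))
        b = np.clip(a + 0.1, 0, 1)
        heat = ssim_map(ImageGrid(a, colorspace="gray"),
                        ImageGrid(b, colorspace="gray"), window=7)
        i = j = 7  # interior pixel, full 7x7 window
        wa = a[i - 3:i + 4, j - 3:j + 4, 0].ravel()
        wb = b[i - 3:i + 4, j - 3:j + 4, 0].ravel()
        mx, my = wa.mean(), wb.mean()
        cov_norm = 1 / (wa.size - 1)
        vx = cov_norm * np.sum((wa - mx) ** 2)
        vy = cov_norm * np.sum((wb - my) ** 2)
        vxy = cov_norm * np.sum((wa - mx) * (wb - my))
        c1, c2 = 0.01 ** 2, 0.03 ** 2
        ssim = ((2 * mx * my + c1) * (2 * vxy + c2)
                / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
        assert heat.values[i, j] == pytest.approx(1 - ssim, rel=1e-9)
        assert heat.values[i, j] > 0  # offset drives similarity below 1

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a = ImageGrid(rng.uniform(0, 1, (16, 16, 3)))
        b = ImageGrid(rng.uniform(0, 1, (16, 16, 3)))
        np.testing.assert_allclose(ssim_map(a, b).values,
                                   ssim_map(b, a).values, atol=1e-9)

    def test_window_larger_than_image_rejected(self):
        x = ImageGrid(np.zeros((5, 5, 3)))
        with pytest.raises(ValueError, match="window"):
            ssim_map(x, x, window=7)


class TestPerceptualMap:
    def test_identical_inputs_give_zero_map(self, rand_backend):
        x = ImageGrid(np.random.default_rng(0).uniform(0, 1, (32, 32, 3)))
        np.testing.assert_allclose(
            perceptual_map(rand_backend, x, x).values, 0.0, atol=1e-12)

    def test_spatial_mean_consistent_with_scalar_distance(self, rand_backend):
        rng = np.random.default_rng(7)
        x = ImageGrid(rng.uniform(0, 1, (32, 32, 3)))
        y = ImageGrid(rng.uniform(0, 1, (32, 32, 3)))
        heat = perceptual_map(rand_backend, x, y)
        d = rand_backend.distance(x, y)
        assert float(heat.values.mean()) == pytest.approx(d, rel=0.02)

    def test_localizes_planted_anomaly(self, rand_backend):
        """The argmax of the perceptual difference map falls inside the
        planted oral/nasal defect on at least 9 of 10 seeded fixtures."""
        hits = 0
        for seed in range(10):
            spec = FixtureSpec(seed=seed)
            planted, base, lm, _ = graded_faces([1.0], spec)[0]
            heat = perceptual_map(rand_backend, planted, base)
            mask = build_mask(lm, "oral_nasal", planted.height)
            r, c = np.unravel_index(np.argmax(heat.values), heat.values.shape)
            hits += bool(mask.mask[r, c])
        assert hits >= 9


class TestErode:
    def test_constant_image_unchanged(self):
        img = ImageGrid(np.full((8, 8, 3), 0.4))
        np.testing.assert_array_equal(erode(img).pixels, img.pixels)

    def test_single_bright_pixel_removed(self):
        a = np.zeros((7, 7, 1))
        a[3, 3, 0] = 1.0
        out = erode(ImageGrid(a, colorspace="gray"))
        assert np.all(out.pixels == 0)

    def test_matches_brute_force_min_filter(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (10, 9, 3))
        out = erode(ImageGrid(a)).pixels
        for i in range(10):
            for j in range(9):
                lo_i, hi_i = max(i - 1, 0), min(i + 2, 10)
                lo_j, hi_j = max(j - 1, 0), min(j + 2, 9)
                for c in range(3):
                    assert out[i, j, c] == a[lo_i:hi_i, lo_j:hi_j, c].min()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_anti_extensive_channelwise(self, seed):
        a = np.random.default_rng(seed).uniform(0, 1, (9, 9, 3))
        assert np.all(erode(ImageGrid(a)).pixels <= a)


def test_pipeline_composition_identity():
    """Any transform chain applied to both inputs yields a zero PSE map."""
    rng = np.random.default_rng(9)
    x = ImageGrid(rng.uniform(0, 1, (16, 16, 3)))
    t = erode(rgb_to_ycbcr(x))
    assert np.all(pse_map(t, t).values == 0)


def test_heatmap_rejects_negative_values():
    with pytest.raises(ValueError, match="nonnegative"):
        Heatmap(np.full((4, 4), -1.0), method="PSE")


def test_masked_mean_increases_with_planted_amplitude():
    """Monotone localization: every heatmap method sees strictly more masked
    energy as the planted defect grows."""
    spec = FixtureSpec(seed=0)
    amplitudes = [0.2, 0.5, 1.0]
    pairs = graded_faces(amplitudes, spec)
    from cleftscore.perceptual import RandomConvPerceptual
    backend = RandomConvPerceptual(seed=0)
    mask = build_mask(pairs[0][2], "oral_nasal", pairs[0][0].height).mask
    for method in ("pse", "ssim", "perceptual"):
        means = []
        for planted, base, lm, _ in pairs:
            if method == "pse":
                heat = pse_map(planted, base)
            elif method == "ssim":
                heat = ssim_map(planted, base)
            else:
                heat = perceptual_map(backend, planted, base)
            means.append(heat.values[mask].mean())
        assert means[0] < means[1] < means[2], method
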