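"""Registration, white balance, CIELab, texture features, SOM and xi_t."""

import numpy as np
import pandas as pd
import pytest

from coralwatch import colorseries as cs
from coralwatch import synth
from coralwatch.imagery import ImageFrame


@pytest.fixture(scope="module")
def scene_frame(small_scene):
    region, centres = small_scene
    truth = synth.SceneTruth(region, [(x, y, "inactive") for x, y in centres],
                             redness_a=8.0)
    return synth.generate_reef_frame(truth, seed=2), truth


@pytest.fixture(scope="module")
def labeller(scene_frame):
    frame, truth = scene_frame
    feats = cs.extract_gabor_features(frame)
    rng = np.random.default_rng(0)
    xs, ys, labels = [], [], []
    for cls, where in ((cs.CORAL, truth.coral_region),
                       (cs.BACKGROUND, ~truth.coral_region)):
        idx = np.argwhere(where)
        pick = idx[rng.choice(len(idx), 2000, replace=False)]
        xs.append(feats[pick[:, 0], pick[:, 1]])
        labels.append(np.full(len(pick), cls))
    return cs.train_pixel_labeller(np.concatenate(xs), np.concatenate(labels),
                                   seed=1)


class TestRegistration:
    def test_frame_against_itself_zero_shift(self, scene_frame):
        frame, _ = scene_frame
        _, shift = cs.register_frame(frame, frame)
        assert shift == (0, 0)

    def test_known_translation_recovered(self, small_scene):
        region, centres = small_scene
        polyps = [(x, y, "inactive") for x, y in centres]
        ref = synth.generate_reef_frame(
            synth.SceneTruth(region, polyps, 0.0), seed=2)
        moved = synth.generate_reef_frame(
            synth.SceneTruth(region, polyps, 0.0, frame_shift=(5, -3)), seed=2)
        aligned, shift = cs.register_frame(moved, ref)
        assert shift == (5, -3)
        # aligned content matches the reference away from the border
        core = np.s_[10:-10, 10:-10]
        assert np.mean(aligned.pixels[core] == ref.pixels[core]) > 0.99

    def test_pure_noise_pair_fails(self):
        rng = np.random.default_rng(0)
        a = ImageFrame("2015-01-01", rng.integers(0, 255, (128, 128, 3), dtype=np.uint8))
        b = ImageFrame("2015-01-01", rng.integers(0, 255, (128, 128, 3), dtype=np.uint8))
        with pytest.raises(cs.AlignmentError):
            cs.register_frame(a, b)

    def test_blank_frame_fails(self, scene_frame):
        frame, _ = scene_frame
        blank = ImageFrame("2015-01-01", np.zeros_like(frame.pixels))
        with pytest.raises(cs.AlignmentError):
            cs.register_frame(blank, frame)


class TestWhiteBalance:
    def test_unit_gains_are_identity(self, scene_frame):
        frame, _ = scene_frame
        out = cs.white_balance(frame, (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(out.pixels, frame.pixels)

    def test_channel_scaling(self):
        frame = ImageFrame("2015-01-01", np.full((4, 4, 3), 100, np.uint8))
        out = cs.white_balance(frame, (2.0, 1.0, 1.0))
        assert tuple(out.pixels[0, 0]) == (200, 100, 100)

    def test_fixed_gains_preserve_relative_differences(self):
        rng = np.random.default_rng(1)
        a = ImageFrame("2015-01-01", rng.integers(10, 100, (8, 8, 3), dtype=np.uint8))
        b = ImageFrame("2015-01-01", rng.integers(10, 100, (8, 8, 3), dtype=np.uint8))
        gains = (1.5, 1.2, 0.8)
        da = cs.white_balance(a, gains).pixels.astype(float) \
            - cs.white_balance(b, gains).pixels.astype(float)
        expected = (a.pixels.astype(float) - b.pixels.astype(float)) \
            * np.array(gains)
        np.testing.assert_allclose(da, expected, atol=1.0)  # uint8 rounding

    def test_non_positive_gain_rejected(self, scene_frame):
        frame, _ = scene_frame
        with pytest.raises(ValueError):
            cs.white_balance(frame, (0.0, 1.0, 1.0))

    def test_estimated_gains_neutralise_the_patch(self):
        pixels = np.zeros((32, 32, 3), np.uint8)
        pixels[...] = (120, 80, 160)
        frame = ImageFrame("2015-01-01", pixels)
        gains = cs.estimate_white_balance(frame, (0, 0, 16, 16))
        out = cs.white_balance(frame, gains).pixels[0, 0].astype(float)
        assert np.ptp(out) <= 1.0


class TestRgbToLab:
    def test_mid_gray_is_neutral(self):
        gray = np.full((2, 2, 3), 128, np.uint8)
        lab = cs.rgb_to_lab(gray)
        assert abs(lab[0, 0, 1]) < 0.05 and abs(lab[0, 0, 2]) < 0.05

    def test_pure_red_reference_value(self):
        red = np.zeros((1, 1, 3), np.uint8)
        red[0, 0, 0] = 255
        lab = cs.rgb_to_lab(red)
        # sRGB/D65 colorimetric reference for (255,0,0)
        assert lab[0, 0, 1] == pytest.approx(80.09, abs=0.05)

    def test_roundtrip_through_rgb(self):
        from skimage.color import lab2rgb
        rng = np.random.default_rng(2)
        rgb = rng.random((16, 16, 3))
        lab = cs.rgb_to_lab(rgb)
        lab2 = cs.rgb_to_lab(lab2rgb(lab))
        np.testing.assert_allclose(lab2, lab, atol=0.01)


class TestGaborFeatures:
    def test_constant_image_uniform_features(self):
        feats = cs.extract_gabor_features(np.full((64, 64), 50.0))
        for j in range(feats.shape[-1]):
            assert np.ptp(feats[..., j]) < 1e-6

    def test_grating_orientation_selectivity(self):
        bank = cs.GaborBank(frequencies=(0.125,),
                            orientations=(0.0, np.pi / 2),
                            pool_orientations=False, smoothing_sigma=0)
        yy, xx = np.mgrid[0:96, 0:96]
        horizontal_bars = np.cos(2 * np.pi * 0.125 * yy)  # varies along y
        feats = cs.extract_gabor_features(horizontal_bars, bank)
        centre = np.s_[32:64, 32:64]
        # theta=0 kernel responds to variation along its orthogonal axis
        r_theta0 = feats[..., 0][centre].mean()
        r_theta90 = feats[..., 1][centre].mean()
        assert r_theta90 > 3 * r_theta0 or r_theta0 > 3 * r_theta90

    def test_feature_dimension_matches_bank(self):
        img = np.random.default_rng(3).random((32, 32))
        pooled = cs.extract_gabor_features(img, cs.GaborBank())
        assert pooled.shape[-1] == 4
        full = cs.extract_gabor_features(
            img, cs.GaborBank(pool_orientations=False))
        assert full.shape[-1] == 24

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            cs.extract_gabor_features(np.ones((8, 8)),
                                      cs.GaborBank(frequencies=()))


class TestSomLabeller:
    def test_separable_clouds_high_accuracy(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 0.3, (500, 4))
        b = rng.normal(3.0, 0.3, (500, 4))
        x = np.vstack([a, b])
        y = np.r_[np.zeros(500, int), np.ones(500, int)]
        lab = cs.train_pixel_labeller(x[::2], y[::2], seed=0)
        acc = np.mean(lab.predict(x[1::2]) == y[1::2])
        assert acc >= 0.99

    def test_indistinguishable_classes_near_chance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(800, 4))
        y = np.r_[np.zeros(400, int), np.ones(400, int)]
        lab = cs.train_pixel_labeller(x, y, seed=0)
        acc = np.mean(lab.predict(x) == y)
        assert 0.3 <= acc <= 0.7

    def test_same_seed_identical_codebook(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(300, 4))
        y = rng.integers(0, 2, 300)
        l1 = cs.train_pixel_labeller(x, y, seed=3)
        l2 = cs.train_pixel_labeller(x, y, seed=3)
        np.testing.assert_array_equal(l1.codebook, l2.codebook)
        np.testing.assert_array_equal(l1.node_labels, l2.node_labels)

    def test_single_class_rejected(self):
        x = np.random.default_rng(7).normal(size=(50, 4))
        with pytest.raises(ValueError):
            cs.train_pixel_labeller(x, np.zeros(50, int), seed=0)

    def test_hierarchical_refinement_helps_on_overlapping_clouds(self):
        rng = np.random.default_rng(10)
        x = np.vstack([rng.normal(0.0, 1.0, (800, 4)),
                       rng.normal(1.0, 1.0, (800, 4))])
        y = np.r_[np.zeros(800, int), np.ones(800, int)]
        flat = cs.train_pixel_labeller(x, y, seed=0)
        hier = cs.train_pixel_labeller(x, y, seed=0, hierarchical=True)
        assert len(hier.refinements) > 0
        acc_flat = np.mean(flat.predict(x) == y)
        acc_hier = np.mean(hier.predict(x) == y)
        assert acc_hier >= acc_flat - 0.01


class TestSegmentation:
    def test_synthetic_scene_iou(self, scene_frame, labeller):
        frame, truth = scene_frame
        mask = cs.segment_coral(frame, labeller)
        inter = np.logical_and(mask, truth.coral_region).sum()
        union = np.logical_or(mask, truth.coral_region).sum()
        assert inter / union >= 0.9

    def test_all_background_frame_small_mask(self, labeller):
        truth = synth.SceneTruth(np.zeros((320, 320), bool), [], 0.0)
        frame = synth.generate_reef_frame(truth, seed=11)
        mask = cs.segment_coral(frame, labeller)
        assert mask.mean() <= 0.05

    def test_mask_has_frame_dimensions(self, scene_frame, labeller):
        frame, _ = scene_frame
        assert cs.segment_coral(frame, labeller).shape == frame.pixels.shape[:2]


class TestMeanColor:
    def test_uniform_image_any_mask(self):
        lab = np.tile(np.array([50.0, 10.0, -5.0]), (8, 8, 1))
        mask = np.zeros((8, 8), bool)
        mask[2, 3] = True
        assert cs.mean_color(lab, mask) == pytest.approx((50.0, 10.0, -5.0))

    def test_half_and_half_average(self):
        lab = np.zeros((4, 4, 3))
        lab[:2, :, 1] = 0.0
        lab[2:, :, 1] = 10.0
        assert cs.mean_color(lab, None).a == pytest.approx(5.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(8)
        lab = rng.normal(size=(16, 16, 3))
        mask = rng.random((16, 16)) > 0.5
        got = cs.mean_color(lab, mask)
        acc, n = np.zeros(3), 0
        for y in range(16):
            for x in range(16):
                if mask[y, x]:
                    acc += lab[y, x]
                    n += 1
        np.testing.assert_allclose(got, acc / n, rtol=1e-12)

    def test_full_mask_equals_full_image_mean(self):
        rng = np.random.default_rng(9)
        lab = rng.normal(size=(12, 12, 3))
        np.testing.assert_allclose(cs.mean_color(lab, np.ones((12, 12), bool)),
                                   cs.mean_color(lab, None), rtol=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(cs.EmptyMaskError):
            cs.mean_color(np.zeros((4, 4, 3)), np.zeros((4, 4), bool))


@pytest.fixture(scope="module")
def ramp_run(labeller):
    frames, truths = synth.generate_sequence(
        12, np.linspace(0.0, 15.0, 12), 0.3, jitter_sd=1.0,
        missing_fraction=0.0, seed=5, shape=(320, 320), n_polyps=14)
    df = cs.color_series(frames, labeller)
    return frames, truths, df


class TestColorSeries:
    def test_recovers_linear_redness_ramp(self, ramp_run):
        _, truths, df = ramp_run
        truth_a = np.array([t.redness_a for t in truths])
        slope = np.polyfit(np.arange(len(df)), df["xi_a"], 1)[0]
        truth_slope = np.polyfit(np.arange(len(truth_a)), truth_a, 1)[0]
        assert slope == pytest.approx(truth_slope, rel=0.10)
        r = np.corrcoef(df["xi_a"], truth_a)[0, 1]
        assert r >= 0.95

    def test_timestamps_strictly_increasing(self, ramp_run):
        _, _, df = ramp_run
        assert pd.DatetimeIndex(df["timestamp"]).is_monotonic_increasing

    def test_order_permutation_invariance(self, labeller):
        frames, _ = synth.generate_sequence(5, 7.0, 0.3, jitter_sd=0.0,
                                            missing_fraction=0.0, seed=6,
                                            shape=(320, 320), n_polyps=14)
        df1 = cs.color_series(frames, labeller)
        df2 = cs.color_series(frames[::-1], labeller,
                              reference=frames[0])
        np.testing.assert_allclose(df1["xi_a"], df2["xi_a"])

    def test_dropped_frames_appear_as_gaps(self, labeller):
        frames, _ = synth.generate_sequence(10, 7.0, 0.3, jitter_sd=0.0,
                                            missing_fraction=0.3, seed=7,
                                            shape=(320, 320), n_polyps=14)
        df = cs.color_series(frames, labeller)
        present = set(pd.DatetimeIndex(df["timestamp"]))
        all_hours = set(pd.date_range(frames[0].timestamp, periods=10, freq="h"))
        missing = all_hours - present
        assert len(missing) == 10 - len(frames)
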