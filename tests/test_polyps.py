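"""Polyp mask, patch dataset, classifier, gamma_t and the accuracy protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from coralwatch import polyps as pl
from coralwatch import synth
from coralwatch.imagery import ImageFrame


def _ann(rows):
    return pd.DataFrame(rows, columns=["image", "x", "y", "class", "annotator"])


class TestBuildPolypMask:
    def test_minimal_disc_of_radius_one(self):
        ann = _ann([("0", 10, 10, "active", "a")])
        mask = pl.build_polyp_mask(ann, (21, 21), disc_radius=1)
        assert mask.sum() == 5  # centre + 4-neighbourhood
        assert mask[10, 10] and mask[9, 10] and mask[10, 9]

    def test_overlapping_points_union_without_double_count(self):
        one = pl.build_polyp_mask(_ann([("0", 10, 10, "active", "a")]),
                                  (21, 21), 3)
        two = pl.build_polyp_mask(_ann([("0", 10, 10, "active", "a"),
                                        ("0", 10, 10, "inactive", "b")]),
                                  (21, 21), 3)
        np.testing.assert_array_equal(one, two)

    def test_border_point_clipped_to_roi(self):
        mask = pl.build_polyp_mask(_ann([("0", 0, 0, "active", "a")]), (16, 16), 5)
        assert mask.shape == (16, 16) and mask[0, 0]

    def test_empty_annotations_rejected(self):
        with pytest.raises(ValueError):
            pl.build_polyp_mask(_ann([]), (16, 16))


class TestExtractPatches:
    @pytest.fixture()
    def frame(self):
        rng = np.random.default_rng(0)
        return ImageFrame("2015-01-01",
                          rng.integers(0, 255, (128, 128, 3), dtype=np.uint8))

    def test_patch_equals_the_centred_crop(self, frame):
        ps = pl.extract_patches(frame, _ann([("0", 64, 64, "active", "a")]))
        np.testing.assert_array_equal(ps.patches[0],
                                      frame.pixels[41:87, 41:87])
        assert ps.labels[0] == pl.ACTIVE

    def test_border_centre_skipped_and_logged(self, frame):
        ps = pl.extract_patches(frame, _ann([("0", 10, 64, "active", "a")]))
        assert len(ps) == 0
        assert len(ps.skipped) == 1

    def test_n_valid_centres_give_n_patches(self, frame):
        rows = [("0", 30 + 10 * i, 60, "inactive", "a") for i in range(7)]
        assert len(pl.extract_patches(frame, _ann(rows))) == 7


class TestSampleBackground:
    @pytest.fixture()
    def frame(self):
        rng = np.random.default_rng(1)
        return ImageFrame("2015-01-01",
                          rng.integers(0, 255, (128, 128, 3), dtype=np.uint8))

    def test_all_centres_outside_the_mask(self, frame):
        mask = np.zeros((128, 128), bool)
        mask[40:90, 40:90] = True
        ps = pl.sample_background(frame, mask, n=30, seed=0)
        for _, row in ps.provenance.iterrows():
            assert not mask[row["y"], row["x"]]

    def test_single_feasible_centre_found(self, frame):
        mask = np.ones((128, 128), bool)
        mask[64, 64] = False
        ps = pl.sample_background(frame, mask, n=1, seed=0)
        assert (ps.provenance.loc[0, "x"], ps.provenance.loc[0, "y"]) == (64, 64)

    def test_shortfall_error_names_the_counts(self, frame):
        mask = np.ones((128, 128), bool)
        with pytest.raises(ValueError, match="0 feasible"):
            pl.sample_background(frame, mask, n=10, seed=0)

    def test_deterministic_under_seed(self, frame):
        mask = np.zeros((128, 128), bool)
        a = pl.sample_background(frame, mask, n=20, seed=5)
        b = pl.sample_background(frame, mask, n=20, seed=5)
        np.testing.assert_array_equal(a.patches, b.patches)


class TestAugmentation:
    def _patchset(self, n):
        rng = np.random.default_rng(2)
        if n == 0:
            return pl.PatchSet(np.empty((0, 46, 46, 3), np.uint8),
                               np.empty(0, int), np.empty(0, int),
                               np.empty(0, dtype=object),
                               pd.DataFrame(columns=["image", "x", "y",
                                                     "augmentation"]))
        return pl.PatchSet(
            rng.integers(0, 255, (n, 46, 46, 3), dtype=np.uint8),
            rng.integers(0, 2, n), np.arange(n),
            np.full(n, "train", dtype=object),
            pd.DataFrame({"image": ["0"] * n, "x": 50, "y": 50,
                          "augmentation": "original"}))

    @pytest.mark.parametrize("n,expected", [(1, 48), (0, 0), (5, 240)])
    def test_exact_48_fold_multiplication(self, n, expected):
        assert len(pl.augment_patches(self._patchset(n), seed=0)) == expected

    def test_descendants_inherit_source_and_split(self):
        aug = pl.augment_patches(self._patchset(3), seed=0)
        assert set(aug.source_ids) == {0, 1, 2}
        assert (aug.split == "train").all()
        assert (np.bincount(aug.source_ids) == 48).all()

    def test_identity_member_present(self):
        ps = self._patchset(1)
        aug = pl.augment_patches(ps, seed=0)
        ident = aug.provenance["augmentation"] == "flip=0,rot=0,noise=0"
        assert ident.sum() == 1
        np.testing.assert_array_equal(aug.patches[np.nonzero(ident.to_numpy())[0][0]],
                                      ps.patches[0])


class TestSplit:
    def _sources(self, n):
        rng = np.random.default_rng(3)
        return pl.PatchSet(
            rng.integers(0, 255, (n, 46, 46, 3), dtype=np.uint8),
            np.zeros(n, int), np.arange(n), np.full(n, "", dtype=object),
            pd.DataFrame({"image": ["0"] * n, "x": 50, "y": 50,
                          "augmentation": "original"}))

    def test_hundred_sources_split_70_20_10(self):
        ps = pl.split_dataset(self._sources(100), seed=0)
        counts = pd.Series(ps.split).value_counts()
        assert counts["train"] == 70 and counts["val"] == 20 and counts["test"] == 10

    def test_same_seed_same_assignment(self):
        a = pl.split_dataset(self._sources(50), seed=4)
        b = pl.split_dataset(self._sources(50), seed=4)
        np.testing.assert_array_equal(a.split, b.split)

    def test_no_augmented_descendant_of_heldout_source_in_train(self, annotated_patches):
        augmented, _, _ = annotated_patches
        train_sources = set(augmented.source_ids[augmented.split == "train"])
        for name in ("val", "test"):
            held = set(augmented.source_ids[augmented.split == name])
            assert not (held & train_sources)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            pl.split_dataset(self._sources(10), fractions=(0.7, 0.2, 0.2))
        with pytest.raises(ValueError):
            pl.split_dataset(self._sources(10), fractions=(1.2, -0.4, 0.2))


class TestClassifier:
    def test_separable_synthetic_patches_high_validation_accuracy(self, trained_classifier):
        clf, _ = trained_classifier
        assert clf.metadata["accuracy"]["val"] >= 0.95
        assert clf.metadata["accuracy"]["test"] >= 0.90

    def test_permuted_labels_give_chance_accuracy(self, annotated_patches):
        augmented, _, _ = annotated_patches
        rng = np.random.default_rng(0)
        shuffled = pl.PatchSet(augmented.patches,
                               rng.permutation(augmented.labels),
                               augmented.source_ids, augmented.split,
                               augmented.provenance)
        clf = pl.train_classifier(shuffled, pl.TrainSpec(epochs=1, seed=0))
        counts = np.bincount(shuffled.for_split("val").labels,
                             minlength=len(pl.CLASSES))
        chance = counts.max() / counts.sum()
        assert clf.metadata["accuracy"]["val"] <= chance + 0.15

    def test_output_is_a_probability(self, trained_classifier):
        clf, _ = trained_classifier
        rng = np.random.default_rng(1)
        tiles = rng.integers(0, 255, (16, 46, 46, 3), dtype=np.uint8)
        lik = clf.activity_likelihood(tiles)
        assert np.all(lik >= 0) and np.all(lik <= 1)

    def test_missing_class_in_train_rejected(self):
        rng = np.random.default_rng(4)
        n = 30
        ps = pl.PatchSet(
            rng.integers(0, 255, (n, 46, 46, 3), dtype=np.uint8),
            np.r_[np.zeros(10, int), np.ones(10, int), np.full(10, 2)],
            np.arange(n),
            np.array(["train"] * 10 + ["val"] * 10 + ["train"] * 10,
                     dtype=object),
            pd.DataFrame({"image": ["0"] * n, "x": 50, "y": 50,
                          "augmentation": "original"}))
        with pytest.raises(ValueError, match="absent"):
            pl.train_classifier(ps, pl.TrainSpec(epochs=1))

    def test_save_load_roundtrip(self, trained_classifier, tmp_path):
        clf, _ = trained_classifier
        clf.save(tmp_path / "clf.npz")
        other = pl.Classifier.load(tmp_path / "clf.npz")
        rng = np.random.default_rng(2)
        tiles = rng.integers(0, 255, (4, 46, 46, 3), dtype=np.uint8)
        np.testing.assert_array_equal(clf.predict_proba(tiles),
                                      other.predict_proba(tiles))


class _ConstantClassifier:
    """Test double returning a fixed likelihood for every patch."""

    def __init__(self, value, size=46):
        from coralwatch._lenet import LeNet5
        self.net = LeNet5(input_size=size)
        self.value = value

    def activity_likelihood(self, patches):
        return np.full(len(patches), self.value, dtype=np.float32)


class TestClassifyPixels:
    def test_constant_one_classifier_marks_all_masked_pixels(self):
        frame = ImageFrame("2015-01-01", np.zeros((64, 64, 3), np.uint8))
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        lik = pl.classify_pixels(frame, mask, _ConstantClassifier(1.0), stride=1)
        assert np.all(lik[mask] == 1.0)
        assert pl.polyp_activity(lik >= 0.5, mask) == 1.0

    def test_pixels_outside_mask_never_evaluated(self):
        frame = ImageFrame("2015-01-01", np.zeros((64, 64, 3), np.uint8))
        mask = np.zeros((64, 64), bool)
        mask[30:34, 30:34] = True
        lik = pl.classify_pixels(frame, mask, _ConstantClassifier(0.7), stride=1)
        assert np.isnan(lik[~mask]).all()

    def test_stride_one_equals_brute_force_oracle(self, trained_classifier,
                                                  small_sequence):
        """Dense classification must equal an independent per-pixel loop that
        crops each patch and calls the classifier itself."""
        clf, _ = trained_classifier
        frames, _ = small_sequence
        frame = frames[3]
        mask = np.zeros(frame.pixels.shape[:2], bool)
        mask[100:124, 150:174] = True  # a small ROI keeps the loop honest
        lik = pl.classify_pixels(frame, mask, clf, stride=1)
        size = 46
        half = size // 2
        padded = np.pad(frame.pixels, ((half, half), (half, half), (0, 0)),
                        mode="reflect")
        tiles, coords = [], []
        for y in range(frame.pixels.shape[0]):
            for x in range(frame.pixels.shape[1]):
                if mask[y, x]:
                    tiles.append(padded[y:y + size, x:x + size])
                    coords.append((y, x))
        expected = clf.activity_likelihood(np.stack(tiles))
        got = np.array([lik[y, x] for y, x in coords])
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_larger_stride_changes_gamma_only_slightly(self, trained_classifier,
                                                       small_sequence):
        clf, mask = trained_classifier
        frames, _ = small_sequence
        frame = frames[5]
        g1 = pl.polyp_activity(
            pl.classify_pixels(frame, mask, clf, stride=2) >= 0.5, mask)
        g4 = pl.polyp_activity(
            pl.classify_pixels(frame, mask, clf, stride=4) >= 0.5, mask)
        assert abs(g1 - g4) <= 0.05

    def test_empty_mask_rejected(self, trained_classifier):
        clf, _ = trained_classifier
        frame = ImageFrame("2015-01-01", np.zeros((64, 64, 3), np.uint8))
        with pytest.raises(ValueError):
            pl.classify_pixels(frame, np.zeros((64, 64), bool), clf)


class TestPolypActivity:
    def test_all_active_is_one_none_is_zero(self):
        mask = np.ones((10, 10), bool)
        assert pl.polyp_activity(np.ones((10, 10), bool), mask) == 1.0
        assert pl.polyp_activity(np.zeros((10, 10), bool), mask) == 0.0

    def test_direct_count(self):
        mask = np.ones((10, 10), bool)
        active = np.zeros((10, 10), bool)
        active.flat[:37] = True
        assert pl.polyp_activity(active, mask) == pytest.approx(0.37)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            pl.polyp_activity(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_gamma_bounded_and_monotone_in_active_set(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) > 0.3
        if not mask.any():
            mask[0, 0] = True
        active = rng.random((16, 16)) > 0.5
        g = pl.polyp_activity(active, mask)
        assert 0.0 <= g <= 1.0
        more = active | (rng.random((16, 16)) > 0.7)
        assert pl.polyp_activity(more, mask) >= g


class TestActivitySeries:
    def test_ramp_recovered_in_rank_order(self, trained_classifier, small_sequence):
        clf, mask = trained_classifier
        frames, truths = small_sequence
        df = pl.activity_series(frames, mask, clf, stride=4)
        truth = [t.active_fraction for t in truths]
        rho = spearmanr(df["gamma"], truth).statistic
        assert rho >= 0.9

    def test_gamma_stays_in_unit_interval(self, trained_classifier, small_sequence):
        clf, mask = trained_classifier
        frames, _ = small_sequence
        df = pl.activity_series(frames[:3], mask, clf, stride=6)
        assert df["gamma"].between(0, 1).all()


class TestObserverAgreement:
    def test_identical_sets_agree_perfectly(self):
        a = _ann([("0", 10, 10, "active", "a"), ("0", 40, 40, "inactive", "a")])
        assert pl.observer_agreement(a, a.assign(annotator="b")) == 1.0

    def test_disjoint_locations_agree_zero(self):
        a = _ann([("0", 10, 10, "active", "a")])
        b = _ann([("0", 200, 200, "active", "b")])
        assert pl.observer_agreement(a, b) == 0.0

    def test_eight_of_ten_matched_pairs(self):
        rows_a, rows_b = [], []
        for i in range(10):
            cls_b = "active" if i < 8 else "inactive"
            rows_a.append(("0", 50 * i, 50, "active", "a"))
            rows_b.append(("0", 50 * i + 3, 52, cls_b, "b"))
        assert pl.observer_agreement(_ann(rows_a), _ann(rows_b)) \
            == pytest.approx(0.8)

    def test_unmatched_points_count_as_disagreement(self):
        a = _ann([("0", 10, 10, "active", "a"), ("0", 300, 300, "active", "a")])
        b = _ann([("0", 10, 10, "active", "b")])
        assert pl.observer_agreement(a, b) == pytest.approx(0.5)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            pl.observer_agreement(_ann([]), _ann([]))


class TestManualGamma:
    def test_all_active(self):
        assert pl.manual_gamma(_ann([("0", 1, 1, "active", "a")])) == 1.0

    def test_three_of_twelve(self):
        rows = [("0", 10 * i, 10, "active" if i < 3 else "inactive", "a")
                for i in range(12)]
        assert pl.manual_gamma(_ann(rows)) == pytest.approx(0.25)

    def test_mask_filter_applies(self):
        mask = np.zeros((64, 64), bool)
        mask[:, :32] = True
        rows = [("0", 10, 10, "active", "a"), ("0", 50, 10, "inactive", "a")]
        assert pl.manual_gamma(_ann(rows), mask) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pl.manual_gamma(_ann([]))
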