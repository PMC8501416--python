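"""Accuracy surfaces, confusion metrics, majority decisions, the mode
noise filter, and false-RGB rendering."""

import numpy as np
import pytest

import snapmsi as sm
from snapmsi.evaluate import (
    ClassificationMap,
    majority_accuracy,
    map_from_predictions,
)
from snapmsi.raw import ImageCube, MASK_SATURATED, MASK_VALID


class TestPerPixelAccuracy:
    def test_all_correct(self):
        assert sm.per_pixel_accuracy(np.ones(10), np.ones(10)) == 100.0

    def test_three_of_four(self):
        assert sm.per_pixel_accuracy(
            np.array([1, 1, 1, 0]), np.array([1, 1, 1, 1])
        ) == 75.0

    def test_masked_pixels_fully_excluded(self, rng):
        """Loop oracle that skips masked entries."""
        pred = rng.integers(0, 3, 50)
        truth = rng.integers(0, 3, 50)
        mask = rng.random(50) > 0.4
        got = sm.per_pixel_accuracy(pred, truth, mask)
        num = den = 0
        for p, t, m in zip(pred, truth, mask):
            if m:
                den += 1
                num += p == t
        assert got == pytest.approx(100.0 * num / den)

    def test_no_valid_pixels_rejected(self):
        with pytest.raises(ValueError):
            sm.per_pixel_accuracy(np.ones(4), np.ones(4), np.zeros(4, dtype=bool))


class TestPerImageAccuracy:
    def test_unweighted_mean_of_image_accuracies(self):
        preds = [np.array([1, 1]), np.array([1, 0])]
        truths = [1, 1]
        mean, sd, excluded = sm.per_image_accuracy(preds, truths)
        assert mean == 75.0
        assert sd == pytest.approx(25.0)
        assert excluded == 0

    def test_single_image_sd_zero(self):
        mean, sd, _ = sm.per_image_accuracy([np.array([1, 1, 0])], [1])
        assert mean == pytest.approx(100 * 2 / 3)
        assert sd == 0.0

    def test_unweighted_differs_from_pixel_weighted(self):
        """Two images with different sizes: the unweighted mean weights
        both images equally, unlike pooled per-pixel accuracy."""
        preds = [np.ones(100), np.array([0, 1])]  # 100% and 50%
        truths = [1, 1]
        mean, _, _ = sm.per_image_accuracy(preds, truths)
        pooled = sm.per_pixel_accuracy(
            np.concatenate(preds), np.ones(102)
        )
        assert mean == 75.0
        assert pooled == pytest.approx(100.0 * 101 / 102)

    def test_empty_images_excluded_and_counted(self):
        mean, _, excluded = sm.per_image_accuracy(
            [np.array([1]), np.array([])], [1, 1]
        )
        assert mean == 100.0
        assert excluded == 1


class TestMajorityPerImage:
    def test_plurality_wins(self):
        preds = np.array([0] * 10 + [1] * 5 + [2])
        assert sm.majority_per_image(preds, 0) == (True, False)

    def test_two_way_tie_counts_incorrect(self):
        preds = np.array([0] * 8 + [1] * 8)
        correct, tied = sm.majority_per_image(preds, 0)
        assert not correct
        assert tied

    def test_unanimous_image(self):
        preds = np.zeros(1280, dtype=int)
        assert sm.majority_per_image(preds, 0)[0]
        assert not sm.majority_per_image(preds, 1)[0]

    def test_three_way_tie_counts_incorrect(self):
        preds = np.array([0, 1, 2])
        correct, tied = sm.majority_per_image(preds, 0)
        assert not correct and tied

    def test_majority_accuracy_aggregates(self):
        per_image = [np.array([0, 0, 1]), np.array([1, 1]), np.array([0, 1])]
        acc, ties, excluded = majority_accuracy(per_image, [0, 1, 0])
        assert acc == pytest.approx(100 * 2 / 3)
        assert ties == 1
        assert excluded == 0


class TestConfusionMetrics:
    def test_two_by_two_formula_oracle(self):
        truths = np.array([1] * 10 + [0] * 10)
        preds = np.array([1] * 9 + [0] + [0] * 10)
        cm, m = sm.confusion_and_metrics(preds, truths, classes=[0, 1], positive_class=1)
        assert m.tp == 9 and m.fn == 1 and m.tn == 10 and m.fp == 0
        assert m.sensitivity == pytest.approx(90.0)
        assert m.specificity == pytest.approx(100.0)
        assert m.ppv == pytest.approx(100.0)
        assert m.npv == pytest.approx(100 * 10 / 11)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1])
        _, m = sm.confusion_and_metrics(y, y, classes=[0, 1], positive_class=1)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (100.0,) * 4

    def test_degenerate_all_positive_predictions(self):
        truths = np.array([0, 0, 1, 1])
        preds = np.ones(4, dtype=int)
        _, m = sm.confusion_and_metrics(preds, truths, classes=[0, 1], positive_class=1)
        assert m.specificity == 0.0
        assert m.npv is None  # undefined, not 0

    def test_confusion_rows_sum_to_class_counts(self, rng):
        truths = rng.integers(0, 3, 200)
        preds = rng.integers(0, 3, 200)
        cm, _ = sm.confusion_and_metrics(preds, truths, classes=[0, 1, 2])
        assert np.array_equal(cm.sum(axis=1), np.bincount(truths, minlength=3))

    def test_accuracy_reconciles_with_confusion_trace(self, rng):
        truths = rng.integers(0, 3, 500)
        preds = rng.integers(0, 3, 500)
        cm, _ = sm.confusion_and_metrics(preds, truths, classes=[0, 1, 2])
        acc = sm.per_pixel_accuracy(preds, truths)
        assert acc == pytest.approx(100.0 * np.trace(cm) / cm.sum())


class TestModeNoiseFilter:
    def _map(self, labels, mask=None):
        labels = np.asarray(labels)
        if mask is None:
            mask = np.zeros(labels.shape, dtype=np.uint8)
        return ClassificationMap(labels, mask)

    def test_uniform_map_unchanged(self):
        m = self._map(np.ones((5, 5), dtype=int))
        out = sm.mode_noise_filter(m)
        assert np.array_equal(out.labels, m.labels)

    def test_isolated_pixel_replaced_by_neighbor_class(self):
        labels = np.ones((5, 5), dtype=int)
        labels[2, 2] = 0
        out = sm.mode_noise_filter(self._map(labels))
        assert out.labels[2, 2] == 1

    def test_pixel_with_one_agreeing_neighbor_kept(self):
        labels = np.ones((5, 5), dtype=int)
        labels[2, 2] = 0
        labels[2, 3] = 0
        out = sm.mode_noise_filter(self._map(labels))
        assert out.labels[2, 2] == 0

    def test_tie_resolves_to_lowest_class_index(self):
        labels = np.full((3, 3), 0, dtype=int)
        labels[1, 1] = 0
        labels[0, 1], labels[2, 1] = 1, 1
        labels[1, 0], labels[1, 2] = 2, 2
        out = sm.mode_noise_filter(self._map(labels))
        assert out.labels[1, 1] == 1  # {1, 1, 2, 2} -> lowest tied class

    def test_exhaustive_four_neighbor_multisets_match_rule_oracle(self):
        """Enumerate every 4-neighbor class combination around a center
        pixel and compare to a direct statement of the rule."""
        from itertools import product

        for center in range(3):
            for neigh in product(range(3), repeat=4):
                labels = np.full((3, 3), center, dtype=int)
                labels[0, 1], labels[1, 0], labels[1, 2], labels[2, 1] = neigh
                out = sm.mode_noise_filter(self._map(labels))
                if all(v != center for v in neigh):
                    vals, counts = np.unique(neigh, return_counts=True)
                    expected = vals[counts == counts.max()].min()
                else:
                    expected = center
                assert out.labels[1, 1] == expected, (center, neigh)

    def test_border_pixels_use_available_neighbors(self):
        labels = np.ones((3, 3), dtype=int)
        labels[0, 0] = 0  # corner: 2 neighbors, both class 1
        out = sm.mode_noise_filter(self._map(labels))
        assert out.labels[0, 0] == 1

    def test_masked_neighbors_ignored(self):
        labels = np.ones((3, 3), dtype=int)
        labels[1, 1] = 0
        mask = np.zeros((3, 3), dtype=np.uint8)
        mask[0, 1] = MASK_SATURATED
        out = sm.mode_noise_filter(self._map(labels, mask))
        assert out.labels[1, 1] == 1  # remaining 3 valid neighbors all differ

    def test_single_pass_removes_all_isolated_defects(self, rng):
        """Contraction property: any number of non-adjacent single-pixel
        defects disappears in one pass."""
        labels = np.zeros((12, 12), dtype=int)
        spots = [(1, 1), (1, 5), (4, 3), (7, 7), (10, 2), (5, 10)]
        for r, c in spots:
            labels[r, c] = 1 + (r + c) % 2
        out = sm.mode_noise_filter(self._map(labels))
        assert np.all(out.labels == 0)

    def test_too_small_map_rejected(self):
        with pytest.raises(ValueError):
            sm.mode_noise_filter(self._map(np.zeros((2, 2), dtype=int)))


class TestFalseRgb:
    def _cube(self, values, mask=None):
        if mask is None:
            mask = np.zeros(values.shape[:2], dtype=np.uint8)
        return ImageCube(values, mask)

    def test_constant_cube_renders_flat(self, rng):
        values = np.broadcast_to(rng.uniform(0.2, 0.8, 9), (4, 4, 9)).copy()
        rgb = sm.false_rgb(self._cube(values))
        for ch in range(3):
            assert np.ptp(rgb[:, :, ch]) == 0.0

    def test_masked_pixels_render_white(self, rng):
        values = rng.uniform(0, 1, (4, 4, 9))
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = MASK_SATURATED
        rgb = sm.false_rgb(self._cube(values, mask))
        assert np.all(rgb[0, 0] == 1.0)

    def test_default_and_broadband_assignments(self, rng):
        from snapmsi.evaluate import FALSE_RGB_BROADBAND, FALSE_RGB_DEFAULT

        assert FALSE_RGB_DEFAULT == (2, 1, 0)
        assert FALSE_RGB_BROADBAND == (1, 2, 8)
        values = rng.uniform(0, 1, (4, 4, 9))
        a = sm.false_rgb(self._cube(values), FALSE_RGB_DEFAULT)
        b = sm.false_rgb(self._cube(values), FALSE_RGB_BROADBAND)
        assert a.shape == b.shape == (4, 4, 3)
        assert not np.allclose(a, b)

    def test_invalid_band_index_rejected(self, rng):
        with pytest.raises(ValueError):
            sm.false_rgb(self._cube(rng.uniform(0, 1, (4, 4, 9))), (0, 1, 9))


class TestMapAssembly:
    def test_predictions_fill_valid_pixels_only(self, rng):
        values = rng.uniform(0, 1, (4, 5, 9))
        mask = np.zeros((4, 5), dtype=np.uint8)
        mask[0, :] = MASK_SATURATED
        cube = ImageCube(values, mask)
        preds = rng.integers(0, 3, int((mask == MASK_VALID).sum()))
        cmap = map_from_predictions(cube, preds)
        assert np.all(cmap.labels[0, :] == -1)
        assert np.array_equal(cmap.labels[mask == MASK_VALID], preds)

    def test_majority_on_images_with_60_percent_correct_pixels(self, rng):
        """If every image has >= 60% correct pixels (3 classes), the
        majority decision is always right."""
        per_image, truths = [], []
        for i in range(50):
            truth = i % 3
            n = 100
            preds = np.full(n, truth)
            wrong = rng.permutation(n)[:40]
            # split the 40% wrong pixels between the other two classes
            others = [c for c in range(3) if c != truth]
            preds[wrong[:20]] = others[0]
            preds[wrong[20:]] = others[1]
            per_image.append(preds)
            truths.append(truth)
        acc, ties, _ = majority_accuracy(per_image, truths)
        assert acc == 100.0
        assert ties == 0
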