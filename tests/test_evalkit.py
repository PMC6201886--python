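"""Evaluation toolkit: accuracy bookkeeping, offset tables, ROC against a
pairwise oracle, published-benchmark aggregates, blur-width estimation."""

import numpy as np
import pandas as pd
import pytest

from deepfocus import benchmarks, blurlab, evalkit as ek


class TestAccuracy:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (ek.ConfusionCounts(3, 2, 4, 4), 0.625),
            (ek.ConfusionCounts(4, 4, 4, 4), 1.0),
            (ek.ConfusionCounts(0, 0, 4, 4), 0.0),
        ],
    )
    def test_definition(self, c, expected):
        assert ek.accuracy(c) == pytest.approx(expected)

    def test_class_swap_invariance(self):
        a = ek.accuracy(ek.ConfusionCounts(3, 1, 5, 2))
        b = ek.accuracy(ek.ConfusionCounts(1, 3, 2, 5))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ek.accuracy(ek.ConfusionCounts(0, 0, 0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ek.ConfusionCounts(5, 0, 4, 4)

    def test_counts_from_predictions(self):
        labels = np.array(["in_focus", "in_focus", "blurred", "blurred"])
        pred = np.array(["in_focus", "blurred", "blurred", "in_focus"])
        c = ek.confusion_counts(labels, pred)
        assert (c.TP, c.TN, c.P, c.N) == (1, 1, 2, 2)


class TestAccuracyByOffset:
    def test_two_slide_hand_case(self):
        rows = []
        for slide, acc in (("s1", 1.0), ("s2", 0.8)):
            n_ok = int(acc * 10)
            for i in range(10):
                rows.append({
                    "slide_id": slide, "offset_um": 1.5, "label": "blurred",
                    "predicted": "blurred" if i < n_ok else "in_focus",
                })
        table = ek.accuracy_by_offset(pd.DataFrame(rows))
        row = table.per_offset.iloc[0]
        assert row["mean_accuracy"] == pytest.approx(0.9)
        assert row["std_accuracy"] == pytest.approx(0.14142, abs=1e-4)

    def test_aggregates_recompute_from_entries(self, small_dataset):
        man = small_dataset.manifest
        rng = np.random.default_rng(2)
        pred = np.where(rng.random(len(man)) < 0.85, man["label"],
                        np.where(man["label"] == "in_focus", "blurred", "in_focus"))
        table = ek.accuracy_by_offset(man.assign(predicted=pred))
        for _, row in table.per_offset.iterrows():
            sub = table.per_slide[table.per_slide["offset_um"] == row["offset_um"]]
            assert row["mean_accuracy"] == pytest.approx(sub["accuracy"].mean())
            if row["n_slides"] > 1:
                assert row["std_accuracy"] == pytest.approx(sub["accuracy"].std(ddof=1))
        assert table.grand_mean == pytest.approx(table.per_offset["mean_accuracy"].mean())

    def test_single_slide_flagged_with_zero_std(self):
        df = pd.DataFrame({
            "slide_id": ["s1"] * 4, "offset_um": [2.0] * 4,
            "label": ["blurred"] * 4, "predicted": ["blurred"] * 4,
        })
        with pytest.warns(UserWarning, match="single slide"):
            table = ek.accuracy_by_offset(df)
        assert table.per_offset.iloc[0]["std_accuracy"] == 0.0
        assert table.per_offset.iloc[0]["n_slides"] == 1

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            ek.accuracy_by_offset(pd.DataFrame({"offset_um": [1.0]}))


class TestPublishedBenchmark:
    """Aggregates of the published per-offset accuracies: the CNN's grand
    mean 93.2% (sample std 9.6%), baseline 69.4%, difference 23.8%."""

    def test_cnn_grand_mean_and_std(self):
        table = ek.OffsetAccuracyTable.from_offset_means(benchmarks.CNN_ACCURACY_BY_OFFSET)
        assert round(table.grand_mean, 1) == 93.2
        assert round(table.grand_std, 1) == 9.6

    def test_baseline_grand_mean(self):
        table = ek.OffsetAccuracyTable.from_offset_means(benchmarks.BASELINE_ACCURACY_BY_OFFSET)
        assert round(table.grand_mean, 1) == 69.4

    def test_method_difference(self):
        cnn = ek.OffsetAccuracyTable.from_offset_means(benchmarks.CNN_ACCURACY_BY_OFFSET)
        base = ek.OffsetAccuracyTable.from_offset_means(benchmarks.BASELINE_ACCURACY_BY_OFFSET)
        diff = ek.compare_methods(cnn, base)
        grand = diff[diff["offset_um"] == "grand_mean"]["abs_difference"].iloc[0]
        assert round(grand, 1) == 23.8


class TestCompareMethods:
    def test_identical_tables_give_zero(self):
        t = ek.OffsetAccuracyTable.from_offset_means({0.0: 90.0, 1.5: 80.0})
        diff = ek.compare_methods(t, t)
        assert (diff["abs_difference"] == 0).all()

    def test_grand_difference_equals_difference_of_grands(self):
        a = ek.OffsetAccuracyTable.from_offset_means({0.0: 90.0, 1.5: 80.0})
        b = ek.OffsetAccuracyTable.from_offset_means({0.0: 70.0, 1.5: 75.0})
        diff = ek.compare_methods(a, b)
        grand = diff[diff["offset_um"] == "grand_mean"]["abs_difference"].iloc[0]
        assert grand == pytest.approx(abs(a.grand_mean - b.grand_mean), abs=1e-9)

    def test_mismatched_offsets_rejected(self):
        a = ek.OffsetAccuracyTable.from_offset_means({0.0: 90.0})
        b = ek.OffsetAccuracyTable.from_offset_means({1.5: 80.0})
        with pytest.raises(ValueError):
            ek.compare_methods(a, b)


def brute_force_auc(scores, y):
    """Mann-Whitney U / (P*N): pairwise win fraction with half-credit ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array(["blurred", "blurred", "in_focus", "in_focus"])
        assert ek.roc_curve(scores, labels).auc == pytest.approx(1.0)

    def test_negating_scores_flips_auc(self, rng):
        scores = rng.random(100)
        labels = np.where(rng.random(100) < 0.4, "in_focus", "blurred")
        auc = ek.roc_curve(scores, labels).auc
        flipped = ek.roc_curve(-scores, labels).auc
        assert auc + flipped == pytest.approx(1.0, abs=1e-9)

    def test_matches_pairwise_u_statistic(self, rng):
        for _ in range(5):
            scores = np.round(rng.random(40), 2)  # rounded -> ties occur
            y = (rng.random(40) < 0.5).astype(int)
            if y.sum() in (0, 40):
                continue
            labels = np.where(y == 1, "in_focus", "blurred")
            got = ek.roc_curve(scores, labels).auc
            assert got == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_curve_is_monotone(self, rng):
        scores = rng.random(200)
        labels = np.where(rng.random(200) < 0.5, "in_focus", "blurred")
        roc = ek.roc_curve(scores, labels)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.fpr[0] == 0 and roc.fpr[-1] == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ek.roc_curve(np.array([0.1, 0.9]), np.array(["blurred", "blurred"]))


class TestBlurSigma:
    def test_constant_tile_unidentifiable(self):
        est = ek.estimate_blur_sigma(np.full((64, 64, 3), 0.5))
        assert est.sigma == 0.0 and not est.identifiable

    @staticmethod
    def _pipeline_tile(seed, sigma):
        """A tile as the acquisition pipeline produces it: rendered,
        defocused, plus the sensor-noise floor the estimator models."""
        sharp = blurlab.render_sharp_tile(blurlab.SyntheticTileSpec(seed=seed))
        blurred = blurlab.apply_defocus(sharp, sigma)
        return blurlab.add_sensor_noise(blurred, 0.01, np.random.default_rng(seed + 500))

    def test_recovers_moderate_blur(self):
        est = ek.estimate_blur_sigma(self._pipeline_tile(2, 2.0))
        assert 1.5 <= est.sigma <= 2.5

    def test_sharp_tile_estimates_small_sigma(self):
        # sigma 0.4 is the residual blur of a perfectly focused scan
        est = ek.estimate_blur_sigma(self._pipeline_tile(3, 0.4))
        assert est.sigma <= 0.6 + 1e-9
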