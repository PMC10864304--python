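"""Evaluation metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.metrics import precision_score, recall_score

from markersel.benchmark import (confusion, corrupt_labels, evaluate_markers,
                                 f1_report, jaccard_top_variance,
                                 local_logit_baseline, mean_l1, mean_l2,
                                 misclassification, noise_robustness,
                                 random_marker_baseline, random_method,
                                 spearman_variance)
from markersel.selector import MarkerSet
from markersel.synthetic import gaussian_clusters
from markersel.training import TrainingConfig


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion(["a", "b", "a"], ["a", "b", "a"])
        assert np.array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_enumerated_example(self):
        cm = confusion(["A", "A", "B"], ["A", "B", "B"])
        assert np.array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_total_is_conserved(self):
        rng = np.random.default_rng(0)
        y = rng.choice(list("abc"), 40)
        p = rng.choice(list("abc"), 40)
        assert confusion(y, p).total == 40

    def test_unseen_predicted_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a", "a"], ["a", "z"])


class TestMisclassification:
    def test_diagonal_gives_zero(self):
        cm = confusion(["a", "b"], ["a", "b"])
        per_class, avg = misclassification(cm)
        assert np.allclose(per_class, 0.0) and avg == 0.0

    def test_hand_example(self):
        # counts [[1,1],[0,2]]: M_1 = 1 - 1/1 = 0, M_2 = 1 - 2/3
        cm = confusion(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        per_class, avg = misclassification(cm)
        assert per_class[0] == pytest.approx(0.0)
        assert per_class[1] == pytest.approx(1 / 3)
        assert avg == pytest.approx(1 / 6)

    def test_never_predicted_class_warns_and_scores_one(self):
        cm = confusion(["a", "b"], ["a", "a"])
        with pytest.warns(UserWarning):
            per_class, _ = misclassification(cm)
        assert per_class[1] == 1.0

    def test_single_class_degenerate(self):
        cm = confusion(["a", "a"], ["a", "a"])
        _, avg = misclassification(cm)
        assert avg == 0.0


class TestF1:
    def test_perfect(self):
        cm = confusion(["a", "b", "b"], ["a", "b", "b"])
        f1, macro, weighted = f1_report(cm)
        assert np.allclose(f1, 1.0) and macro == 1.0 and weighted == 1.0

    def test_hand_example(self):
        # class A: P=1, R=1/2 -> 2/3; class B: P=2/3, R=1 -> 4/5
        cm = confusion(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        f1, macro, _ = f1_report(cm)
        assert f1[0] == pytest.approx(2 / 3)
        assert f1[1] == pytest.approx(4 / 5)
        assert macro == pytest.approx(11 / 15)

    def test_balanced_support_makes_macro_equal_weighted(self):
        cm = confusion(["a", "a", "b", "b"], ["a", "b", "b", "a"])
        _, macro, weighted = f1_report(cm)
        assert macro == pytest.approx(weighted)


def test_metrics_agree_with_sklearn_on_random_confusions():
    """Oracle equivalence on 100 random small label configurations."""
    rng = np.random.default_rng(1)
    for _ in range(100):
        C = rng.integers(2, 7)
        n = rng.integers(2 * C, 60)
        classes = [chr(97 + i) for i in range(C)]
        y = rng.choice(classes, n)
        while len(np.unique(y)) < C:
            y = rng.choice(classes, n)
        p = rng.choice(classes, n)
        cm = confusion(y, p)
        with np.errstate(all="ignore"):
            prec = precision_score(y, p, labels=classes, average=None,
                                   zero_division=0.0)
            rec = recall_score(y, p, labels=classes, average=None,
                               zero_division=0.0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_class, avg = misclassification(cm)
        predicted = cm.counts.sum(axis=0)
        expect_m = np.where(predicted > 0, 1.0 - prec, 1.0)
        assert np.allclose(per_class, expect_m)
        f1, macro, weighted = f1_report(cm)
        denom = prec + rec
        expect_f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
        assert np.allclose(f1, expect_f1)
        assert macro == pytest.approx(expect_f1.mean())


class TestReconstructionMetrics:
    def _scaled(self, scales, seed=0, n=200):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((n, len(scales)))
        base = base - base.mean(axis=0)
        return base * np.asarray(scales)

    def test_identical_matrices(self):
        X = self._scaled([1, 2, 3, 4, 5, 6])
        assert jaccard_top_variance(X, X) == 1.0
        assert spearman_variance(X, X) == pytest.approx(1.0)
        assert mean_l2(X, X) == 0.0 and mean_l1(X, X) == 0.0

    def test_disjoint_top_sets(self):
        scales_a = [10, 9, 1, 1, 1, 1, 1, 1, 1, 1]
        scales_b = [1, 1, 10, 9, 1, 1, 1, 1, 1, 1]
        base = self._scaled([1] * 10, seed=1)
        assert jaccard_top_variance(base * scales_a, base * scales_b) == 0.0

    def test_partial_overlap_one_third(self):
        # top-2 sets {3, 7} vs {3, 9} -> |{3}| / |{3,7,9}| = 1/3
        scales_a = np.ones(10); scales_a[3], scales_a[7] = 9, 8
        scales_b = np.ones(10); scales_b[3], scales_b[9] = 9, 8
        base = self._scaled([1] * 10, seed=2)
        assert jaccard_top_variance(base * scales_a, base * scales_b) == pytest.approx(1 / 3)

    def test_reversed_variance_order(self):
        X = self._scaled([1, 2, 3, 4])
        Y = self._scaled([4, 3, 2, 1], seed=3)
        assert spearman_variance(X, Y) == pytest.approx(-1.0)

    def test_spearman_hand_example(self):
        # variance ranks (1,2,3,4) vs (2,1,3,4) -> rho = 0.8
        X = self._scaled([8, 6, 4, 2], seed=4)
        Y = self._scaled([6, 8, 4, 2], seed=5)
        assert spearman_variance(X, Y) == pytest.approx(0.8)

    def test_l2_l1_hand_example(self):
        X = np.array([[3.0, 4.0]])
        Z = np.zeros((1, 2))
        assert mean_l2(X, Z) == pytest.approx(5.0)
        assert mean_l1(X, Z) == pytest.approx(7.0)

    def test_agrees_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n, d = int(rng.integers(5, 30)), int(rng.integers(5, 25))
            X = rng.standard_normal((n, d)) * rng.uniform(0.5, 3.0, d)
            Y = rng.standard_normal((n, d)) * rng.uniform(0.5, 3.0, d)
            # brute-force top-variance sets
            top = int(np.floor(d / 5))
            ra = rankdata(-X.var(axis=0), method="average")
            rb = rankdata(-Y.var(axis=0), method="average")
            sa = {i for i in range(d) if ra[i] <= top}
            sb = {i for i in range(d) if rb[i] <= top}
            assert jaccard_top_variance(X, Y) == pytest.approx(
                len(sa & sb) / len(sa | sb))
            # brute-force rank-Pearson
            expect_rho = np.corrcoef(ra, rb)[0, 1]
            assert spearman_variance(X, Y) == pytest.approx(expect_rho)
            # brute-force norms
            l2 = np.mean([np.sqrt(((X[i] - Y[i]) ** 2).sum()) for i in range(n)])
            l1 = np.mean([np.abs(X[i] - Y[i]).sum() for i in range(n)])
            assert mean_l2(X, Y) == pytest.approx(l2)
            assert mean_l1(X, Y) == pytest.approx(l1)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 12)) * rng.uniform(0.5, 2.0, 12)
        Y = rng.standard_normal((30, 12)) * rng.uniform(0.5, 2.0, 12)
        perm = rng.permutation(12)
        assert jaccard_top_variance(X, Y) == pytest.approx(
            jaccard_top_variance(X[:, perm], Y[:, perm]))
        assert spearman_variance(X, Y) == pytest.approx(
            spearman_variance(X[:, perm], Y[:, perm]))


class TestEvaluateMarkers:
    def test_full_panel_on_separable_data(self, small_clusters):
        ds, _ = small_clusters
        from markersel.data_io import split_dataset
        sp = split_dataset(ds, seed=0)
        train = ds.subset_cells(np.concatenate([sp.train_idx, sp.val_idx]))
        test = ds.subset_cells(sp.test_idx)
        markers = MarkerSet(indices=list(range(ds.n_genes)),
                            scores=[1.0] * ds.n_genes, budget=ds.n_genes)
        report = evaluate_markers(train, test, markers)
        assert report.accuracy > 0.95
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion.counts) / report.confusion.total)

    def test_noise_panel_is_at_chance(self, small_clusters):
        ds, truth = small_clusters
        from markersel.data_io import split_dataset
        sp = split_dataset(ds, seed=0)
        train = ds.subset_cells(np.concatenate([sp.train_idx, sp.val_idx]))
        test = ds.subset_cells(sp.test_idx)
        noise_genes = [i for i in range(ds.n_genes)
                       if i not in truth.informative_genes][:6]
        markers = MarkerSet(indices=noise_genes, scores=[1.0] * 6, budget=6)
        report = evaluate_markers(train, test, markers, seed=0)
        assert abs(report.accuracy - 1 / 3) < 0.2

    def test_empty_marker_set_rejected(self, small_clusters):
        ds, _ = small_clusters
        with pytest.raises(ValueError):
            evaluate_markers(ds, ds, MarkerSet([], [], budget=0))


class TestCorruptLabels:
    def test_zero_fraction_is_identity(self):
        y = np.array(["a", "b", "c"] * 10)
        out = corrupt_labels(y, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, y)

    def test_full_fraction_resamples_uniformly(self):
        y = np.array(["a"] * 5000 + ["b"] * 5000)
        out = corrupt_labels(y, 1.0, np.random.default_rng(1))
        assert abs((out == "a").mean() - 0.5) < 0.03

    def test_expected_changed_fraction(self):
        # C = 5, fraction 0.4 -> changed = 0.4 * (1 - 1/5) = 0.32
        rng = np.random.default_rng(2)
        y = rng.choice(list("abcde"), 100_000)
        out = corrupt_labels(y, 0.4, rng)
        assert abs((out != y).mean() - 0.32) < 0.01


class TestBaselines:
    def test_random_baseline_exhaustive_and_deterministic(self):
        assert sorted(random_marker_baseline(5, 5, 0).indices) == list(range(5))
        a = random_marker_baseline(30, 4, seed=3)
        b = random_marker_baseline(30, 4, seed=3)
        assert a.indices == b.indices

    def test_random_baseline_marginal_frequency(self):
        counts = np.zeros(10)
        for seed in range(2000):
            for i in random_marker_baseline(10, 2, seed).indices:
                counts[i] += 1
        assert np.abs(counts / 2000 - 0.2).max() < 0.03

    def test_oversized_k_rejected(self):
        with pytest.raises(ValueError):
            random_marker_baseline(3, 4, 0)

    def test_local_logit_baseline_ignores_ema_momentum(self, small_clusters):
        ds, _ = small_clusters
        base = TrainingConfig(mode="supervised", seed=0, learning_rate=5e-4,
                              max_epochs=3, min_epochs=2)
        import dataclasses
        a = local_logit_baseline(ds, 4, dataclasses.replace(base, ema_momentum=0.5))
        b = local_logit_baseline(ds, 4, dataclasses.replace(base, ema_momentum=0.9))
        assert a.indices == b.indices
        assert len(set(a.indices)) == 4


class TestNoiseRobustness:
    def test_zero_fraction_equals_clean_pipeline(self, small_clusters):
        ds, _ = small_clusters
        curve = noise_robustness(ds, random_method, [0.0], k=6,
                                 protocol="noisy_both", seeds=(0,))
        from markersel.data_io import split_dataset
        sp = split_dataset(ds, seed=0)
        train = ds.subset_cells(np.concatenate([sp.train_idx, sp.val_idx]))
        test = ds.subset_cells(sp.test_idx)
        report = evaluate_markers(train, test, random_method(train, 6, 0), seed=0)
        assert curve["mean_accuracy"][0] == pytest.approx(report.accuracy)

    def test_selection_only_protocol_trains_classifier_on_clean_labels(self, small_clusters):
        ds, _ = small_clusters
        a = noise_robustness(ds, random_method, [0.0, 1.0], k=6,
                             protocol="noisy_selection_only", seeds=(0,))
        # random selection ignores labels entirely -> identical accuracy
        assert a["mean_accuracy"][0] == pytest.approx(a["mean_accuracy"][1])
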