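"""Metrics, stratified folding, cross-validation bookkeeping and sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammocad.evaluation import (
    ConfusionCounts,
    MethodConfig,
    component_sweep,
    compute_metrics,
    crossvalidate,
    stratified_kfold,
)
from mammocad.synthetic import SynthParams, generate_dataset


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(TP=80, FN=20, TN=0, FP=0),
             {"accuracy": 0.80, "sensitivity": 0.80, "specificity": None}),
            (ConfusionCounts(TP=25, TN=25, FP=25, FN=25),
             {"accuracy": 0.50, "sensitivity": 0.50, "specificity": 0.50}),
            (ConfusionCounts(TP=93, FN=7, TN=85, FP=15),
             {"accuracy": 0.89, "sensitivity": 0.93, "specificity": 0.85}),
        ],
    )
    def test_hand_computed_values(self, counts, expected):
        m = compute_metrics(counts)
        for key, val in expected.items():
            if val is None:
                assert m[key] is None
            else:
                assert m[key] == pytest.approx(val)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    def test_accuracy_decomposes_over_classes(self, tp, tn, fp, fn):
        """accuracy = (sens*P + spec*N) / (P + N) whenever defined."""
        c = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
        m = compute_metrics(c)
        P, N = tp + fn, tn + fp
        if P and N:
            combined = (m["sensitivity"] * P + m["specificity"] * N) / (P + N)
            assert m["accuracy"] == pytest.approx(combined)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1)


class TestStratifiedKFold:
    def test_paper_scale_fold_sizes(self):
        """3240 mass + 1850 non-mass split 10 ways: every fold holds
        exactly 324 mass and 185 non-mass (509 test / 4581 train)."""
        labels = np.array(["mass"] * 3240 + ["non-mass"] * 1850)
        folds = stratified_kfold(labels, 10, seed=0)
        for f in range(10):
            mask = folds == f
            assert np.count_nonzero(mask & (labels == "mass")) == 324
            assert np.count_nonzero(mask & (labels == "non-mass")) == 185
            assert np.count_nonzero(mask) == 509
            assert np.count_nonzero(~mask) == 4581

    def test_small_balanced_case(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        folds = stratified_kfold(labels, 5, seed=1)
        for f in range(5):
            assert np.count_nonzero((folds == f) & (labels == "a")) == 1
            assert np.count_nonzero((folds == f) & (labels == "b")) == 1

    def test_near_balance_when_counts_not_divisible(self):
        labels = np.array(["a"] * 13 + ["b"] * 7)
        folds = stratified_kfold(labels, 4, seed=3)
        for cls in ("a", "b"):
            per_fold = [np.count_nonzero((folds == f) & (labels == cls))
                        for f in range(4)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_deterministic_and_seed_sensitive(self):
        labels = np.array(["a"] * 30 + ["b"] * 30)
        f1 = stratified_kfold(labels, 5, seed=9)
        f2 = stratified_kfold(labels, 5, seed=9)
        f3 = stratified_kfold(labels, 5, seed=10)
        np.testing.assert_array_equal(f1, f2)
        assert np.any(f1 != f3)

    def test_class_smaller_than_k_rejected(self):
        labels = np.array(["a"] * 3 + ["b"] * 20)
        with pytest.raises(ValueError, match="fewer than"):
            stratified_kfold(labels, 5)


class TestCrossvalidate:
    def test_every_sample_tested_exactly_once(self, small_dataset):
        report = crossvalidate(small_dataset, "pca", 5, k=5, seed=0)
        total = sum(sum(e["counts"].values()) for e in report.per_fold)
        assert total == small_dataset.n_samples
        assert len(report.per_fold) == 5

    def test_means_are_fold_averages(self, small_dataset):
        report = crossvalidate(small_dataset, "pca", 5, k=5, seed=0)
        accs = [e["metrics"]["accuracy"] for e in report.per_fold]
        assert report.mean_accuracy == pytest.approx(np.mean(accs), abs=1e-12)

    def test_high_separability_all_methods(self, separable_dataset):
        for method in ("pca", "ica", "gabor"):
            report = crossvalidate(separable_dataset, method, 15, k=5, seed=0)
            assert report.mean_accuracy >= 0.9, method

    def test_permuted_labels_score_near_majority_rate(self):
        """Leak canary: with labels shuffled independently of the pixels,
        held-out accuracy must sit at the majority-class rate; any
        train/test leakage in extractor or selection would inflate it."""
        ds = generate_dataset({"mass": 120, "non-mass": 80},
                              SynthParams(blob_contrast=1.5, seed=19))
        rng = np.random.default_rng(5)
        ds.labels = rng.permutation(ds.labels)
        report = crossvalidate(ds, "pca", 10, k=5, seed=0)
        majority = 120 / 200
        assert abs(report.mean_accuracy - majority) < 0.1

    def test_accuracy_increases_with_blob_contrast(self):
        """Monotone on average across 3 contrast levels x 5 seeds."""
        mean_acc = []
        for contrast in (0.2, 0.7, 1.5):
            accs = []
            for seed in range(5):
                ds = generate_dataset(
                    {"mass": 40, "non-mass": 40},
                    SynthParams(blob_contrast=contrast, seed=100 + seed))
                accs.append(
                    crossvalidate(ds, "pca", 5, k=4, seed=seed).mean_accuracy)
            mean_acc.append(np.mean(accs))
        assert mean_acc[0] < mean_acc[1] < mean_acc[2]

    def test_benign_malignant_runs_identical_machinery(self):
        ds = generate_dataset({"benign": 30, "malignant": 30},
                              SynthParams(blob_contrast=1.5, seed=23))
        report = crossvalidate(ds, "pca", 5, k=5, seed=0)
        assert report.config["positive_class"] == "malignant"
        assert 0.0 <= report.mean_accuracy <= 1.0

    def test_non_binary_labels_rejected(self):
        ds = generate_dataset(
            {"mass": 10, "non-mass": 10, "benign": 10},
            SynthParams(seed=2))
        with pytest.raises(ValueError, match="binary"):
            crossvalidate(ds, "pca", 3, k=2, seed=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="svm"):
            MethodConfig(method="svm")


class TestComponentSweep:
    def test_table_matches_requested_grid(self, small_dataset):
        table = component_sweep(small_dataset, "pca", range(1, 11),
                                k=3, seed=0)
        assert list(table.columns) == ["method", "n_components", "accuracy",
                                       "sensitivity", "specificity"]
        assert len(table) == 10
        assert table["n_components"].tolist() == list(range(1, 11))

    def test_sweep_consistent_with_single_crossvalidate(self, small_dataset):
        """A sweep row must reproduce the standalone CV at that count."""
        table = component_sweep(small_dataset, "pca", [4, 8], k=3, seed=5)
        single = crossvalidate(small_dataset, "pca", 8, k=3, seed=5)
        row = table[table.n_components == 8].iloc[0]
        assert row["accuracy"] == pytest.approx(single.mean_accuracy)

    def test_argmax_exists_on_separable_data(self, separable_dataset):
        table = component_sweep(separable_dataset, "pca", range(1, 16),
                                k=3, seed=0)
        best = table.loc[table["accuracy"].idxmax()]
        assert 1 <= best["n_components"] <= 15
        assert best["accuracy"] > 0.9

    def test_empty_range_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="positive"):
            component_sweep(small_dataset, "pca", [], k=3, seed=0)
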