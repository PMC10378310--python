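import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import planted_dataset
from spreadfs import (ConfusionCounts, ExperimentConfig, LabeledDataset,
                      SelectionConfig, aggregate_mode, confusion_metrics,
                      evaluate_subset, run_ablation, run_contrast,
                      run_experiment, split_dataset, two_phase_select)


def labels_only_dataset(n, f, seed=0):
    rng = np.random.default_rng(seed)
    n_pos = round(f * n)
    y = np.array([1] * n_pos + [-1] * (n - n_pos))
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    return LabeledDataset(X, y)


class TestSplit:
    def test_stratified_arithmetic(self):
        data = labels_only_dataset(1000, 0.10)
        train, test = split_dataset(data, 0.7, np.random.default_rng(0))
        assert train.class_counts() == (630, 70)
        assert test.class_counts() == (270, 30)

    def test_half_split(self):
        data = labels_only_dataset(20, 0.5)
        train, test = split_dataset(data, 0.5, np.random.default_rng(1))
        assert train.class_counts() == (5, 5) and test.class_counts() == (5, 5)

    def test_seeds_change_partition_not_ratio(self):
        data = labels_only_dataset(200, 0.2)
        a, _ = split_dataset(data, 0.7, np.random.default_rng(2))
        b, _ = split_dataset(data, 0.7, np.random.default_rng(3))
        assert a.class_counts() == b.class_counts()
        assert not a.X.equals(b.X)

    def test_tiny_class_rejected(self):
        data = labels_only_dataset(20, 0.05)  # a single positive
        with pytest.raises(ValueError):
            split_dataset(data, 0.7, np.random.default_rng(0))


class TestConfusionMetrics:
    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(2, 0, 0, 5), (1.0, 1.0, 1.0)),
        (ConfusionCounts(1, 1, 3, 5), (0.5, 0.25, 1 / 3)),
        (ConfusionCounts(0, 2, 3, 5), (0.0, 0.0, 0.0)),
    ])
    def test_hand_counts(self, counts, expected):
        assert confusion_metrics(counts) == pytest.approx(expected)

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 30, size=4)
            p, r, f1 = confusion_metrics(ConfusionCounts(int(tp), int(fp),
                                                         int(fn), int(tn)))
            assert f1 == pytest.approx(2 / (1 / p + 1 / r))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_metrics_bounded_and_consistent(self, tp, fp, fn, tn):
        p, r, f1 = confusion_metrics(ConfusionCounts(tp, fp, fn, tn))
        assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0 and 0.0 <= f1 <= 1.0
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12 or f1 == 0.0


class TestEvaluateSubset:
    def test_perfectly_separable_feature(self):
        data = planted_dataset(seed=0, n=200, f=0.3, with_duplicate=False)
        train, test = split_dataset(data, 0.7, np.random.default_rng(0))
        row = evaluate_subset(train, test, ["K"])
        assert row["precision"] == row["recall"] == row["f1"] == 1.0

    def test_counts_cover_test_set(self):
        data = planted_dataset(seed=1, n=200, f=0.2)
        train, test = split_dataset(data, 0.7, np.random.default_rng(1))
        row = evaluate_subset(train, test, train.feature_names)
        assert sum(row["counts"].values()) == test.n

    def test_invalid_subset_rejected(self):
        data = planted_dataset(seed=2, n=100, f=0.2)
        train, test = split_dataset(data, 0.7, np.random.default_rng(2))
        with pytest.raises(ValueError):
            evaluate_subset(train, test, ["nope"])


@pytest.fixture(scope="module")
def selected():
    data = planted_dataset(seed=7, n=240, f=0.2)
    rng = np.random.default_rng(5)
    train, test = split_dataset(data, 0.7, rng)
    cfg = SelectionConfig()
    sel = two_phase_select(train, cfg, rng)
    return train, test, sel, cfg, rng


class TestContrastAndAblation:
    def test_contrast_table_shape_and_rules(self, selected):
        train, test, sel, cfg, rng = selected
        rows = run_contrast(train, test, sel, cfg, rng)
        for feat in train.feature_names:
            assert rows[feat]["size"] == 1
        assert rows["All"]["size"] == len(train.feature_names)
        # the two phase-2 alternatives are forced to |F**| features
        assert rows["FFS-ReliefF"]["size"] == rows["FFS-SFS"]["size"]
        assert rows["FFS-Weight"]["size"] == rows["FFS-SFS"]["size"]
        assert set(rows["FFS-SFS"]["subset"]) == set(sel.f_double_star)

    def test_ablation_rules(self, selected):
        train, test, sel, cfg, _ = selected
        rows = run_ablation(train, test, sel, cfg)
        assert set(rows["wo_SFS"]["subset"]) == set(sel.f_star)
        assert 2 <= rows["wo_FFS"]["size"] <= 4
        assert len(sel.f_double_star) <= len(sel.f_star)

    def test_imbalanced_baseline_keeps_most_features_when_all_informative(self):
        """RFE on the raw imbalanced split has no pressure to shrink when
        every feature carries signal: it retains (nearly) the full set."""
        rng = np.random.default_rng(8)
        n, d = 400, 5
        X = pd.DataFrame(rng.normal(size=(n, d)),
                         columns=[f"x{j}" for j in range(d)])
        score = X.sum(axis=1) + 0.3 * rng.normal(size=n)
        y = np.where(score > np.quantile(score, 0.8), 1, -1)
        data = LabeledDataset(X, y)
        train, test = split_dataset(data, 0.7, rng)
        from spreadfs import svm_rfe_cv
        trace = svm_rfe_cv(train, folds=10, rng=rng)
        assert len(trace.best_subset) >= d - 1


class TestAggregation:
    def test_modal_subset(self):
        subsets = [["K", "PR"]] * 18 + [["K"]] * 12
        assert aggregate_mode(subsets) == ["K", "PR"]

    def test_all_distinct_prefers_smallest_then_lexicographic(self):
        subsets = [["K", "Ksum"], ["CC"], ["B"], ["K", "C", "B"]]
        assert aggregate_mode(subsets) == ["B"]

    def test_model_level_vote(self):
        modals = [["K", "K2sum"]] * 10
        assert aggregate_mode(modals) == ["K", "K2sum"]


class TestFullRun:
    def test_reduced_experiment_is_deterministic_and_consistent(self):
        """A miniature end-to-end sweep: identical master seeds give byte-
        identical reports, metric identities hold, and modal subsets come
        from the recorded repeats."""
        config = ExperimentConfig(
            models=["BA"], n=80, n_networks=1, repeats=2, sir_runs=30,
            threshold_runs=60, lambda_multipliers=[1.5], f_values=[0.2],
            selection=SelectionConfig(k=3, folds=4),
        )
        r1 = run_experiment(config)
        r2 = run_experiment(config)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)
        cell = r1["models"]["BA"]["networks"][0]["cells"]["lambda=1.5x,f=0.2"]
        for rep in cell["repeats"]:
            for row in rep["contrast"].values():
                p, r, f1 = row["precision"], row["recall"], row["f1"]
                if p > 0 and r > 0:
                    assert f1 == pytest.approx(2 / (1 / p + 1 / r))
            assert set(rep["f_double_star"]) <= set(rep["f_star"])
        assert cell["modal_subset"] in [rep["f_double_star"]
                                        for rep in cell["repeats"]]
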