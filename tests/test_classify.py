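"""Balancing, cross-validation, grid search and reporting protocol."""

import json

import numpy as np
import pandas as pd
import pytest

from ppgloss import (ConfusionCounts, ExperimentConfig, ParamGrid,
                     RecordError, balance_dataset, build_param_grid, report,
                     run_cv, run_experiment)
from ppgloss.classify import _iter_runs, _stratified_folds

from conftest import make_feature_table


class TestParamGrid:
    def test_grid_cardinalities(self):
        grid = build_param_grid()
        assert len(grid.gamma_values) == 7
        assert len(grid.c_values) == 58

    def test_grid_extremes_and_sorting(self):
        grid = build_param_grid()
        assert grid.c_values[0] == 0.01
        assert grid.c_values[-1] == 5e18
        assert list(grid.c_values) == sorted(set(grid.c_values))
        assert grid.gamma_values == (0.001, 0.005, 0.01, 0.05, 0.1, 0.15, 0.2)


class TestBalance:
    def test_imbalanced_cohort_is_undersampled(self):
        table = pd.concat([make_feature_table(29, "BL", -1, 0),
                           make_feature_table(65, "NBL", 0, 1)],
                          ignore_index=True)
        balanced = balance_dataset(table, seed=4)
        assert len(balanced) == 58
        assert (balanced["label"].value_counts() == 29).all()
        assert balance_dataset(table, seed=4).equals(balanced)
        assert not balance_dataset(table, seed=5).equals(balanced)

    def test_already_balanced_kept_intact(self):
        table = pd.concat([make_feature_table(10, "BL", -1, 0),
                           make_feature_table(10, "NBL", 0, 1)],
                          ignore_index=True)
        balanced = balance_dataset(table, seed=0)
        assert sorted(balanced["record_id"]) == sorted(table["record_id"])

    def test_missing_class_rejected(self):
        with pytest.raises(RecordError, match="both classes"):
            balance_dataset(make_feature_table(10, "BL", -1, 0), seed=0)


class TestCV:
    def test_folds_partition_the_dataset(self):
        y = np.array([0] * 29 + [1] * 29)
        folds = _stratified_folds(y, 4, np.random.default_rng(0))
        joined = np.concatenate(folds)
        assert len(joined) == 58
        assert len(np.unique(joined)) == 58
        for f in folds:
            assert 0 < (y[f] == 1).sum() < len(f)  # both classes per fold

    def test_separable_clouds_classified_accurately(self):
        table = pd.concat([make_feature_table(20, "BL", -5, 2),
                           make_feature_table(20, "NBL", 5, 3)],
                          ignore_index=True)
        counts = run_cv(table, gamma=0.001, C=2.0, seed=1)
        assert counts.overall_accuracy >= 95.0

    def test_shuffled_labels_give_chance_accuracy(self):
        table = pd.concat([make_feature_table(20, "BL", -5, 2),
                           make_feature_table(20, "NBL", 5, 3)],
                          ignore_index=True)
        oas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = table.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            oas.append(run_cv(shuffled, gamma=0.001, C=2.0,
                              seed=seed).overall_accuracy)
        assert 35.0 <= np.mean(oas) <= 65.0

    def test_confusion_count_arithmetic(self):
        counts = ConfusionCounts(tp=31, fn=4, tn=30, fp=5)
        assert counts.sensitivity == pytest.approx(88.57, abs=0.01)
        assert counts.specificity == pytest.approx(85.71, abs=0.01)
        assert counts.overall_accuracy == pytest.approx(87.14, abs=0.01)


@pytest.fixture(scope="module")
def classes():
    return (make_feature_table(12, "BL", -1, 7),
            make_feature_table(20, "NBL", 0, 8))


class TestExperiment:

    def test_runs_per_cell_and_balance(self, classes):
        bl, nbl = classes
        cfg = ExperimentConfig(seed=3)
        grid = ParamGrid(gamma_values=(0.01,), c_values=(2.0,))
        result = run_experiment(bl, nbl, cfg, grid)
        assert result.n_runs == 100
        # every run tests each of the 2*12 balanced records exactly once
        assert (result.counts[:, 0, 0, :].sum(axis=1) == 24).all()

    def test_single_cell_equals_direct_cv(self, classes):
        bl, nbl = classes
        cfg = ExperimentConfig(n_resamples=3, n_permutations=2, seed=9)
        grid = ParamGrid(gamma_values=(0.05,), c_values=(5.0,))
        result = run_experiment(bl, nbl, cfg, grid)
        manual = []
        for dataset, seeds in _iter_runs(bl, nbl, cfg):
            cc = run_cv(dataset, 0.05, 5.0, 4, seed=seeds["fold_seed"])
            manual.append([cc.tp, cc.fn, cc.tn, cc.fp])
        assert np.array_equal(result.counts[:, 0, 0, :], np.array(manual))

    def test_experiment_is_deterministic(self, classes):
        bl, nbl = classes
        cfg = ExperimentConfig(n_resamples=2, n_permutations=2, seed=5)
        grid = ParamGrid(gamma_values=(0.01, 0.1), c_values=(1.0, 100.0))
        r1 = run_experiment(bl, nbl, cfg, grid)
        r2 = run_experiment(bl, nbl, cfg, grid)
        assert np.array_equal(r1.counts, r2.counts)
        assert (r1.optimal_gamma, r1.optimal_c) == (r2.optimal_gamma, r2.optimal_c)

    def test_balanced_oa_is_mean_of_sensitivity_specificity(self, classes):
        bl, nbl = classes
        cfg = ExperimentConfig(n_resamples=2, n_permutations=2, seed=1)
        grid = ParamGrid(gamma_values=(0.01,), c_values=(2.0,))
        result = run_experiment(bl, nbl, cfg, grid)
        assert result.oa[0, 0] == pytest.approx(
            (result.sensitivity[0, 0] + result.specificity[0, 0]) / 2.0,
            abs=1e-9)

    def test_report_matrix_and_json_round_trip(self, classes):
        bl, nbl = classes
        cfg = ExperimentConfig(n_resamples=2, n_permutations=2, seed=1)
        grid = ParamGrid(gamma_values=(0.01, 0.1), c_values=(1.0, 10.0))
        result = run_experiment(bl, nbl, cfg, grid)
        payload, table = report(result)
        cm = payload["confusion_matrix_pct"]
        assert sum(cm["true_BL"].values()) == pytest.approx(100.0)
        assert sum(cm["true_NBL"].values()) == pytest.approx(100.0)
        oa = np.array(payload["overall_accuracy_pct"])
        gi, ci = np.unravel_index(np.argmax(oa), oa.shape)
        assert payload["optimal"]["overall_accuracy_pct"] == pytest.approx(
            oa[gi, ci])
        assert json.loads(json.dumps(payload)) == payload
        assert "True BL" in table
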