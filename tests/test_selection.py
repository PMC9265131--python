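"""Metrics, repeated CV, SSA-LSSVM coupling, baselines, experiments."""

import numpy as np
import pandas as pd
import pytest

import milkpredict as mp
from milkpredict.selection import (
    CVConfig,
    compare_baselines,
    compute_metrics,
    confusion,
    default_ssa_config,
    f_measure,
    fit_ssa_lssvm,
    fold_hash,
    lssvm_factory,
    make_folds,
    repeated_kfold,
)


class TestConfusionAndMetrics:
    def test_perfect_agreement(self):
        c = confusion(np.array([1, 1, -1]), np.array([1, 1, -1]))
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)
        assert all(v == 1.0 for v in compute_metrics(c).values())

    def test_total_inversion(self):
        c = confusion(np.array([1, -1]), np.array([-1, 1]))
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 1, 1)

    def test_counts_partition_sample(self, rng):
        y_true = rng.choice([-1, 1], size=100)
        y_pred = rng.choice([-1, 1], size=100)
        assert confusion(y_true, y_pred).total == 100

    def test_symmetric_case_all_half(self):
        m = compute_metrics(mp.ConfusionCounts(tp=1, tn=1, fp=1, fn=1))
        assert all(v == 0.5 for v in m.values())

    def test_zero_denominator_conventions(self):
        m = compute_metrics(mp.ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m["precision"] == 0.0 and m["recall"] == 0.0 and m["f_measure"] == 0.0

    def test_against_integer_arithmetic_oracle(self, rng):
        for _ in range(500):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(mp.ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert m["accuracy"] == pytest.approx((tp + tn) / (tp + tn + fp + fn), abs=1e-12)
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            assert m["precision"] == pytest.approx(p, abs=1e-12)
            assert m["recall"] == pytest.approx(r, abs=1e-12)
            expected_f = 2 * p * r / (p + r) if p + r else 0.0
            assert m["f_measure"] == pytest.approx(expected_f, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([1]), np.array([1, -1]))

    def test_f_measure_harmonic(self):
        assert f_measure(0.97, 0.94) == pytest.approx(0.9548, abs=5e-5)
        assert f_measure(0.0, 0.0) == 0.0


class TestFolds:
    def test_bookkeeping_5x10(self, small_herd):
        y = mp.make_labels(small_herd, mp.AMT).values
        folds = make_folds(y, CVConfig(k=5, repetitions=10, seed=1))
        assert len(folds) == 50
        for train_idx, test_idx in folds[:5]:
            assert len(np.intersect1d(train_idx, test_idx)) == 0
            assert len(train_idx) + len(test_idx) == len(y)

    def test_stratification_within_one_sample(self, small_herd):
        y = mp.make_labels(small_herd, mp.AMT).values
        global_pos = (y == 1).sum() / len(y)
        folds = make_folds(y, CVConfig(k=5, repetitions=2, seed=3))
        for _, test_idx in folds:
            n_pos = (y[test_idx] == 1).sum()
            assert abs(n_pos - global_pos * len(test_idx)) <= 1.0

    def test_same_seed_same_folds(self, small_herd):
        y = mp.make_labels(small_herd, mp.AMT).values
        cv = CVConfig(k=5, repetitions=3, seed=11)
        assert fold_hash(make_folds(y, cv)) == fold_hash(make_folds(y, cv))

    def test_tiny_minority_class_rejected(self):
        y = np.array([1] * 20 + [-1] * 2)
        with pytest.raises(ValueError, match="minority"):
            make_folds(y, CVConfig(k=5, repetitions=1, seed=0))


class TestRepeatedKFold:
    def test_report_shape_and_determinism(self, small_herd):
        X = mp.extract_features(small_herd)
        y = mp.make_labels(small_herd, mp.AMT)
        cv = CVConfig(k=5, repetitions=10, seed=2)
        r1 = repeated_kfold(X, y, lssvm_factory(1.0, 1.0), cv=cv)
        assert len(r1.per_fold) == 50
        r2 = repeated_kfold(X, y, lssvm_factory(1.0, 1.0), cv=cv)
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)
        assert set(r1.pooled) == {"accuracy", "precision", "recall", "f_measure"}

    def test_constant_features_fall_back_to_majority_rate(self, rng):
        n = 100
        X = np.ones((n, 3))
        y = np.concatenate([np.ones(70), -np.ones(30)]).astype(int)
        rng.shuffle(y)
        report = repeated_kfold(
            X, y, lssvm_factory(1.0, 1.0), cv=CVConfig(k=5, repetitions=2, seed=4)
        )
        assert report.accuracy == pytest.approx(0.7, abs=0.05)


class TestSSALSSVMCoupling:
    def test_same_seed_gives_same_hyperparameters(self, small_herd):
        X = mp.extract_features(small_herd)
        y = mp.make_labels(small_herd, mp.AMT)
        ssa = default_ssa_config(seed=3, pop_size=8, max_iter=5)
        inner = CVConfig(k=3, repetitions=1, seed=3)
        m1, r1 = fit_ssa_lssvm(X, y, ssa=ssa, inner_cv=inner)
        m2, r2 = fit_ssa_lssvm(X, y, ssa=ssa, inner_cv=inner)
        assert (m1.C, m1.sigma) == (m2.C, m2.sigma)
        assert np.array_equal(r1.history, r2.history)

    def test_model_carries_normalization_state(self, small_herd):
        X = mp.extract_features(small_herd)
        y = mp.make_labels(small_herd, mp.AMT)
        model, _ = fit_ssa_lssvm(
            X, y, ssa=default_ssa_config(seed=1, pop_size=8, max_iter=4),
            inner_cv=CVConfig(k=3, repetitions=1, seed=1),
        )
        assert model.normalization_means is not None
        assert model.feature_names == mp.FULL_FEATURE_SET

    def test_one_class_labels_rejected_before_optimization(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="single class"):
            fit_ssa_lssvm(X, np.ones(20, dtype=int))


class TestCompareBaselines:
    def test_six_rows_identical_folds(self, small_herd):
        X = mp.extract_features(small_herd)
        y = mp.make_labels(small_herd, mp.AMT)
        cv = CVConfig(k=5, repetitions=1, seed=5)
        table, reports = compare_baselines(
            X, y, cv=cv, ssa=default_ssa_config(seed=5, pop_size=8, max_iter=5)
        )
        assert len(table) == 6
        assert set(table["model"]) == {
            "KNN", "NaiveBayes", "DecisionTree", "LDA", "LSSVM", "SSA-LSSVM"
        }
        # paired folds: every report has the same number of per-fold rows
        assert {len(r.per_fold) for r in reports.values()} == {5}

    def test_empty_model_list_gives_empty_table(self, small_herd):
        X = mp.extract_features(small_herd)
        y = mp.make_labels(small_herd, mp.AMT)
        table, reports = compare_baselines(X, y, cv=CVConfig(repetitions=1), models=())
        assert table.empty and not reports

    def test_unknown_model_rejected(self, small_herd):
        X = mp.extract_features(small_herd)
        y = mp.make_labels(small_herd, mp.AMT)
        with pytest.raises(ValueError, match="RandomForest"):
            compare_baselines(X, y, models=("RandomForest",))


class TestFeatureSubset:
    def test_subset_must_be_proper(self, small_herd):
        with pytest.raises(ValueError, match="proper subset"):
            mp.feature_subset_experiment(small_herd, mp.AMT, mp.FULL_FEATURE_SET)

    def test_paired_reports_and_difference(self, small_herd):
        out = mp.feature_subset_experiment(
            small_herd, mp.AMT, mp.REDUCED_FEATURE_SET,
            cv=CVConfig(k=5, repetitions=1, seed=6),
            ssa=default_ssa_config(seed=6, pop_size=8, max_iter=5),
        )
        assert len(out["full"].per_fold) == len(out["subset"].per_fold) == 5
        assert out["difference"]["f_measure"] == pytest.approx(
            out["subset"].f_measure - out["full"].f_measure, abs=1e-12
        )


class TestParallelCoordinatesExport:
    def test_long_format_and_round_trip(self, tmp_path, small_herd):
        X = mp.normalize_features(mp.extract_features(small_herd[:3]))
        y = mp.make_labels(small_herd[:3], mp.AMT)
        path = tmp_path / "pc.csv"
        tidy = mp.export_parallel_coordinates(X, y, path)
        assert len(tidy) == 3 * 5
        back = pd.read_csv(path)
        assert list(back.columns) == ["sample", "feature", "value", "label"]
        for s in range(3):
            assert set(back.loc[back["sample"] == s, "label"]) == {y.values[s]}
        np.testing.assert_allclose(
            back.pivot(index="sample", columns="feature", values="value")[
                list(X.feature_names)
            ].to_numpy(),
            X.values,
            rtol=1e-6,
        )

    def test_raw_matrix_rejected(self, small_herd):
        X = mp.extract_features(small_herd[:3])
        y = mp.make_labels(small_herd[:3], mp.AMT)
        with pytest.raises(ValueError, match="normalized"):
            mp.export_parallel_coordinates(X, y, "unused.csv")
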