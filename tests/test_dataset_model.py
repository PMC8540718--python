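"""Prevalence filtering, [-1,1] scaling, grid search and the two protocols."""

import numpy as np
import pytest

from wristmood.dataset_model import (
    RangeScaler,
    SupervisedDataset,
    SvmConfig,
    drop_rare_classes,
    evaluate_leave_one_day_out,
    evaluate_split,
    grid_search_svm,
    project_labels,
)
from wristmood.ema_labeling import Mood


def _ds(y, X=None, days=None):
    y = np.asarray(y)
    if X is None:
        rng = np.random.default_rng(0)
        X = rng.normal(size=(y.size, 3))
    if days is None:
        days = np.zeros(y.size, dtype=int)
    return SupervisedDataset(X=X, y=y, day_index=days, feature_names=["f0", "f1", "f2"])


def _blobs(n_per_class, centers, sd=0.3, seed=0, n_days=1):
    """Well-separated Gaussian blobs, optionally spread over days."""
    rng = np.random.default_rng(seed)
    X, y, days = [], [], []
    for code, c in centers.items():
        pts = rng.normal(loc=c, scale=sd, size=(n_per_class, len(c)))
        X.append(pts)
        y.extend([code] * n_per_class)
        days.extend(np.arange(n_per_class) % n_days)
    return SupervisedDataset(
        X=np.vstack(X), y=np.array(y), day_index=np.array(days),
        feature_names=[f"f{i}" for i in range(len(next(iter(centers.values()))))],
    )


SEPARABLE = {int(Mood.PLEASURE): (0.0, 0.0), int(Mood.AROUSAL): (4.0, 4.0)}


class TestDropRareClasses:
    def test_boundary_share_is_kept(self):
        ds = _ds([0] * 50 + [1] * 40 + [2] * 10)
        out = drop_rare_classes(ds)
        assert set(out.y) == {0, 1, 2}

    def test_iterative_removal_recomputes_shares(self):
        ds = _ds([0] * 55 + [1] * 40 + [2] * 5)
        out = drop_rare_classes(ds)
        assert set(out.y) == {0, 1}
        counts = np.bincount(out.y)
        assert counts[0] / counts.sum() == pytest.approx(55 / 95)

    def test_single_class_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            drop_rare_classes(_ds([0] * 20))

    def test_terminates_on_many_tiny_classes(self):
        ds = _ds([0] * 60 + [1] * 30 + [2] * 4 + [5] * 3 + [6] * 3)
        out = drop_rare_classes(ds)
        assert set(out.y) == {0, 1}


class TestRangeScaler:
    def test_midpoint_maps_to_zero(self):
        X = np.array([[0.0], [10.0], [5.0]])
        s = RangeScaler().fit(X[:2])
        assert s.transform(X)[2, 0] == pytest.approx(0.0)

    def test_constant_feature_maps_to_zero(self):
        X = np.full((5, 2), 7.0)
        out = RangeScaler().fit(X).transform(X)
        assert np.all(out == 0.0)

    def test_train_set_spans_exact_unit_range(self, rng):
        X = rng.normal(size=(40, 6))
        out = RangeScaler().fit(X).transform(X)
        np.testing.assert_allclose(out.min(axis=0), -1.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=0), 1.0, atol=1e-12)

    def test_test_values_may_exceed_range(self):
        s = RangeScaler().fit(np.array([[0.0], [1.0]]))
        assert s.transform(np.array([[2.0]]))[0, 0] == pytest.approx(3.0)


class TestGridSearch:
    def test_separable_blobs_reach_high_cv_accuracy(self):
        ds = _blobs(30, SEPARABLE)
        C, gamma, acc = grid_search_svm(ds.X, ds.y, SvmConfig(cv_folds=3), seed=0)
        assert acc >= 0.95

    def test_ties_resolve_to_smallest_c_then_gamma(self):
        # perfectly separable at every grid point -> the first grid point wins
        ds = _blobs(30, SEPARABLE, sd=0.05)
        cfg = SvmConfig(c_grid=(1.0, 4.0), gamma_grid=(0.25, 1.0), cv_folds=3)
        C, gamma, acc = grid_search_svm(ds.X, ds.y, cfg, seed=0)
        assert acc == 1.0
        assert (C, gamma) == (1.0, 0.25)

    def test_row_shuffle_invariance_under_fixed_seed(self, rng):
        ds = _blobs(25, SEPARABLE, sd=1.5, seed=3)
        cfg = SvmConfig(c_grid=(1.0, 16.0), gamma_grid=(0.1, 1.0), cv_folds=3)
        ref = grid_search_svm(ds.X, ds.y, cfg, seed=5)
        perm = rng.permutation(len(ds))
        out = grid_search_svm(ds.X[perm], ds.y[perm], cfg, seed=5)
        assert out[:2] == ref[:2]

    def test_too_few_samples_per_class_raises(self):
        ds = _ds([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="folds"):
            grid_search_svm(ds.X, ds.y, SvmConfig(cv_folds=5), seed=0)


FAST = SvmConfig(c_grid=(1.0, 16.0), gamma_grid=(0.1, 1.0), cv_folds=3)


class TestEvaluateSplit:
    def test_perfectly_separable_reaches_100(self):
        ds = _blobs(40, SEPARABLE, sd=0.05)
        report = evaluate_split(ds, FAST, repeats=3, seed=0)
        assert report.accuracy_mean == 100.0
        assert report.accuracy_std == 0.0

    def test_shuffled_labels_sit_at_chance(self, rng):
        ds = _blobs(60, SEPARABLE, sd=0.05)
        y_null = rng.permutation(ds.y)
        null = SupervisedDataset(X=ds.X, y=y_null, day_index=ds.day_index,
                                 feature_names=ds.feature_names)
        report = evaluate_split(null, FAST, repeats=5, seed=1)
        n_test = len(ds) // 4
        mc_sd = 100 * np.sqrt(0.5 * 0.5 / n_test)
        assert abs(report.accuracy_mean - 50.0) <= 3 * mc_sd

    def test_single_repeat_has_zero_std(self):
        ds = _blobs(30, SEPARABLE)
        report = evaluate_split(ds, FAST, repeats=1, seed=0)
        assert report.accuracy_std == 0.0

    def test_confusion_trace_reproduces_accuracy_per_run(self):
        ds = _blobs(40, SEPARABLE, sd=1.2, seed=2)
        report = evaluate_split(ds, FAST, repeats=4, seed=0)
        for acc, conf in zip(report.per_run_accuracy, report.per_run_confusion):
            assert np.trace(conf) / conf.sum() * 100 == pytest.approx(acc, abs=1e-12)

    def test_no_leakage_canary(self, rng):
        """A feature equal to the label on the test rows only must not help."""
        n = 160
        y = np.array([int(Mood.PLEASURE), int(Mood.AROUSAL)] * (n // 2))
        X = rng.normal(size=(n, 4))  # labels are pure noise w.r.t. X
        test_idx = rng.choice(n, n // 4, replace=False)
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        canary = rng.normal(size=n)
        canary[test_idx] = y[test_idx].astype(float)  # reveals test labels
        splits = [(train_idx, test_idx)]

        base = evaluate_split(_wrap(X, y), FAST, splits=splits, seed=0)
        leaky = evaluate_split(_wrap(np.column_stack([X, canary]), y), FAST,
                               splits=splits, seed=0)
        n_test = test_idx.size
        mc_sd = 100 * np.sqrt(0.5 * 0.5 / n_test)
        assert leaky.accuracy_mean <= base.accuracy_mean + 3 * mc_sd
        assert abs(leaky.accuracy_mean - 50.0) <= 3 * mc_sd


def _wrap(X, y):
    return SupervisedDataset(X=X, y=y, day_index=np.zeros(y.size, dtype=int),
                             feature_names=[f"f{i}" for i in range(X.shape[1])])


class TestLeaveOneDayOut:
    def test_identical_days_separable_reach_100(self):
        ds = _blobs(40, SEPARABLE, sd=0.05, n_days=2)
        report = evaluate_leave_one_day_out(ds, FAST, seed=0)
        assert report.accuracy_mean == 100.0
        assert len(report.per_run_accuracy) == 2

    def test_mean_equals_average_of_per_day_accuracies(self):
        ds = _blobs(30, SEPARABLE, sd=1.5, seed=4, n_days=3)
        report = evaluate_leave_one_day_out(ds, FAST, seed=0)
        assert report.accuracy_mean == pytest.approx(np.mean(report.per_run_accuracy))

    def test_class_absent_from_training_counts_as_errors(self):
        # day 1 holds the only arousal rows: when held out, they cannot be
        # predicted and per-day accuracy reflects that
        X = np.vstack([np.zeros((20, 2)), np.ones((10, 2)) * 4])
        y = np.array([int(Mood.PLEASURE)] * 20 + [int(Mood.AROUSAL)] * 10)
        days = np.array([0] * 10 + [1] * 10 + [1] * 10)
        extra = np.array([int(Mood.CONTENTMENT)] * 10)
        X = np.vstack([X, np.full((10, 2), -4.0)])
        y = np.concatenate([y, extra])
        days = np.concatenate([days, [0] * 10])
        ds = SupervisedDataset(X=X, y=y, day_index=days, feature_names=["a", "b"])
        report = evaluate_leave_one_day_out(ds, FAST, seed=0)
        day1 = report.per_run_accuracy[1]
        assert day1 <= 50.0  # ten arousal rows of twenty are unpredictable

    def test_single_day_rejected(self):
        ds = _blobs(20, SEPARABLE)
        with pytest.raises(ValueError, match="2 distinct days"):
            evaluate_leave_one_day_out(ds, FAST)


class TestProjectLabels:
    def test_pleasure_projection_groups_by_valence_sign(self):
        ds = _ds([int(Mood.PLEASURE), int(Mood.DISPLEASURE), int(Mood.AROUSAL),
                  int(Mood.EXCITEMENT)])
        out = project_labels(ds, "pleasure")
        assert out.y.tolist() == [2, 0, 1, 2]

    def test_arousal_projection_groups_by_arousal_sign(self):
        ds = _ds([int(Mood.SLEEPINESS), int(Mood.AROUSAL), int(Mood.PLEASURE)])
        out = project_labels(ds, "arousal")
        assert out.y.tolist() == [0, 2, 1]
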