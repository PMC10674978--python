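import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from cecgstress.classify import (
    FEATURE_COLUMNS,
    UNDEFINED,
    ConfusionCounts,
    MetricsReport,
    SplitScheme,
    compute_metrics,
    cross_validate,
    predict,
    train_classifier,
    zscore_normalize,
)
from oracles import naive_metrics


def _table(X: np.ndarray, y: np.ndarray, subjects) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df["label"] = np.where(y == 1, "high_stress", "low_stress")
    df["subject"] = subjects
    return df


def _gaussian_dataset(rng, n_per_class=100, sep=6.0, n_subjects=10):
    """Two Gaussian clusters separated by `sep` SDs along two features."""
    X0 = rng.normal(0.0, 1.0, (n_per_class, 4))
    X1 = rng.normal(0.0, 1.0, (n_per_class, 4))
    X1[:, 0] += sep
    X1[:, 1] += sep
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    subj = [f"s{i % n_subjects}" for i in range(n_per_class)] * 2
    return X, y, subj


class TestZscoreNormalize:
    def test_basic_column(self):
        df = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in FEATURE_COLUMNS})
        out, (mean, sd) = zscore_normalize(df)
        np.testing.assert_allclose(out[FEATURE_COLUMNS[0]], [-1.0, 0.0, 1.0])
        assert sd[FEATURE_COLUMNS[0]] == 1.0  # sample SD convention

    def test_idempotent_with_fitted_stats(self, rng):
        df = pd.DataFrame(rng.normal(2, 3, (50, 4)), columns=FEATURE_COLUMNS)
        out, stats = zscore_normalize(df)
        again, _ = zscore_normalize(out)
        np.testing.assert_allclose(again[FEATURE_COLUMNS].to_numpy(),
                                   out[FEATURE_COLUMNS].to_numpy(), atol=1e-12)

    def test_training_stats_apply_to_test(self, rng):
        train = pd.DataFrame(rng.normal(5, 2, (40, 4)), columns=FEATURE_COLUMNS)
        test = pd.DataFrame(rng.normal(5, 2, (10, 4)), columns=FEATURE_COLUMNS)
        _, stats = zscore_normalize(train)
        out, _ = zscore_normalize(test, stats=stats)
        expected = (test[FEATURE_COLUMNS] - stats[0]) / stats[1]
        np.testing.assert_allclose(out[FEATURE_COLUMNS].to_numpy(), expected.to_numpy())

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in FEATURE_COLUMNS})
        df["pnn50"] = 0.5
        with pytest.raises(ValueError, match="pnn50"):
            zscore_normalize(df)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(5, 0, 5, 0))
        assert r.balanced_accuracy == 100.0
        assert r.sensitivity == r.specificity == r.ppv == r.npv == 1.0
        assert r.mcc == 1.0

    def test_no_positives_undefined(self):
        # classifier never sees or predicts positives: sensitivity and BA
        # have no denominator, like the published all-negative SVM case
        r = compute_metrics(ConfusionCounts(0, 3, 7, 0))
        assert r.sensitivity is UNDEFINED
        assert r.balanced_accuracy is UNDEFINED
        assert r.specificity == 0.7

    def test_hand_evaluation(self):
        r = compute_metrics(ConfusionCounts(tp=3, fn=1, tn=4, fp=2))
        assert r.sensitivity == pytest.approx(0.75)
        assert r.specificity == pytest.approx(2 / 3)
        assert r.balanced_accuracy == pytest.approx(70.8333333333)
        assert r.ppv == pytest.approx(0.6)
        assert r.npv == pytest.approx(0.8)
        assert r.mcc == pytest.approx(10 / np.sqrt(600))

    def test_exhaustive_grid_against_oracle(self):
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            got = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            want = naive_metrics(tp, fp, tn, fn)
            for key, expected in want.items():
                value = getattr(got, key)
                if expected is None:
                    assert value is UNDEFINED, (key, tp, fp, tn, fn)
                else:
                    assert value == pytest.approx(expected), (key, tp, fp, tn, fn)

    def test_label_swap_symmetry(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 20, 4)
            if tp + fp + tn + fn == 0:
                continue
            a = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            b = compute_metrics(ConfusionCounts(tn, fn, tp, fp))
            assert a.sensitivity == b.specificity
            assert a.ppv == b.npv
            if a.balanced_accuracy is not UNDEFINED and b.balanced_accuracy is not UNDEFINED:
                assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy)
            if a.mcc is not UNDEFINED and b.mcc is not UNDEFINED:
                assert abs(a.mcc) == pytest.approx(abs(b.mcc))

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 1, 0)


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["knn", "svm", "ann"])
    def test_separable_clusters_high_accuracy(self, rng, kind):
        X, y, subj = _gaussian_dataset(rng)
        half = rng.permutation(len(y))
        tr, te = half[:100], half[100:]
        Xz = (X - X[tr].mean(0)) / X[tr].std(0, ddof=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_classifier(kind, Xz[tr], y[tr], seed=0)
        y_pred = predict(model, Xz[te])
        tp = np.sum((y[te] == 1) & (y_pred == 1))
        tn = np.sum((y[te] == 0) & (y_pred == 0))
        fp = np.sum((y[te] == 0) & (y_pred == 1))
        fn = np.sum((y[te] == 1) & (y_pred == 0))
        ba = compute_metrics(ConfusionCounts(tp, fp, tn, fn)).balanced_accuracy
        assert ba >= 95.0

    def test_knn_k1_memorizes_training_set(self, rng):
        X, y, _ = _gaussian_dataset(rng, n_per_class=30, sep=1.0)
        from sklearn.neighbors import KNeighborsClassifier

        model = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_ann_deterministic(self, rng):
        X, y, _ = _gaussian_dataset(rng, n_per_class=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = train_classifier("ann", X, y, seed=5)
            b = train_classifier("ann", X, y, seed=5)
        np.testing.assert_array_equal(predict(a, X), predict(b, X))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_classifier("knn", np.zeros((5, 4)), np.zeros(5, int))

    def test_unknown_kind_raises(self, rng):
        X, y, _ = _gaussian_dataset(rng, n_per_class=5)
        with pytest.raises(ValueError):
            train_classifier("forest", X, y)


class TestCrossValidate:
    def test_perfectly_separable_feature(self, rng):
        X, y, subj = _gaussian_dataset(rng, sep=50.0)
        cv = cross_validate(_table(X, y, subj), "knn", SplitScheme(5, seed=1))
        ba = cv["aggregate"]["balanced_accuracy"]
        assert ba["mean"] == 100.0 and ba["sd"] == 0.0

    def test_label_permutation_near_chance(self, rng):
        X, y, subj = _gaussian_dataset(rng, sep=6.0)
        y_perm = rng.permutation(y)
        cv = cross_validate(_table(X, y_perm, subj), "knn", SplitScheme(5, seed=2))
        ba = cv["aggregate"]["balanced_accuracy"]
        assert 40.0 <= ba["mean"] <= 60.0

    def test_grouped_partition_arithmetic(self, rng):
        X, y, subj = _gaussian_dataset(rng, n_per_class=50, n_subjects=10)
        df = _table(X, y, subj)
        from cecgstress.classify import _grouped_folds

        masks = _grouped_folds(df["subject"].to_numpy(), 5, seed=0)
        for m in masks:
            assert df.loc[m, "subject"].nunique() == 2
        total = np.sum([m.sum() for m in masks])
        assert total == len(df)

    def test_subjects_never_straddle_folds(self, rng):
        X, y, subj = _gaussian_dataset(rng)
        from cecgstress.classify import _grouped_folds

        masks = _grouped_folds(np.asarray(subj), 5, seed=3)
        for s in set(subj):
            in_fold = [bool(m[np.asarray(subj) == s].any()) for m in masks]
            assert sum(in_fold) == 1

    def test_no_leakage_of_test_rows(self, rng):
        """Perturbing held-out rows must not change fitted normalization."""
        X, y, subj = _gaussian_dataset(rng, n_per_class=50)
        df = _table(X, y, subj)
        from cecgstress.classify import _grouped_folds

        test_mask = _grouped_folds(df["subject"].to_numpy(), 5, seed=4)[0]
        _, stats_a = zscore_normalize(df.loc[~test_mask])
        df2 = df.copy()
        df2.loc[test_mask, FEATURE_COLUMNS] += 1e6
        _, stats_b = zscore_normalize(df2.loc[~test_mask])
        pd.testing.assert_series_equal(stats_a[0], stats_b[0])
        pd.testing.assert_series_equal(stats_a[1], stats_b[1])

    def test_too_few_subjects_raises(self, rng):
        X, y, _ = _gaussian_dataset(rng, n_per_class=10)
        df = _table(X, y, ["s0"] * 10 + ["s1"] * 10)
        with pytest.raises(ValueError):
            cross_validate(df, "knn", SplitScheme(5, seed=0))

    def test_undefined_fold_metrics_counted(self, rng):
        # a fold whose test subjects are all negative has no sensitivity;
        # the aggregate must count it instead of averaging it in
        n = 20
        X = rng.normal(0, 1, (5 * n, 4))
        X[:, 0] += np.repeat([0, 0, 5, 5, 0], n)  # s2, s3 positive-shifted
        y = np.repeat([0, 0, 1, 1, 0], n)
        subj = np.repeat([f"s{i}" for i in range(5)], n)
        df = _table(X, y, subj)
        cv = cross_validate(df, "knn", SplitScheme(5, seed=0))
        agg = cv["aggregate"]["sensitivity"]
        assert agg["n_undefined"] >= 1
        undefined_folds = [r for r in cv["folds"] if r.sensitivity is UNDEFINED]
        assert len(undefined_folds) == agg["n_undefined"]

    def test_ann_separable_ba(self, rng):
        X, y, subj = _gaussian_dataset(rng, sep=6.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = cross_validate(_table(X, y, subj), "ann", SplitScheme(5, seed=5))
        assert cv["aggregate"]["balanced_accuracy"]["mean"] >= 95.0
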