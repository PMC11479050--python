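"""Split protocol, model tuning, metrics and permutation importance."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_toy_table
from tonus import classify as clf
from tonus.classify import (
    CLASS_ORDER,
    FEATURE_COLUMNS,
    MODEL_KINDS,
    ModelResult,
    SplitSpec,
)


def table_with_counts(counts: dict[str, int], seed=0, subjects_per_class=5):
    rng = np.random.default_rng(seed)
    rows, labels, subjects = [], [], []
    for cls, n in counts.items():
        for i in range(n):
            rows.append(rng.normal(size=len(FEATURE_COLUMNS)))
            labels.append(cls)
            subjects.append(f"{cls[:2]}{i % subjects_per_class}")
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df["label"] = labels
    df.index = pd.Index(subjects, name="subject_id")
    return df


class TestSplit:
    def test_585_rows_split_468_117(self):
        # the full cohort's class row counts: 150/150/135/150
        df = table_with_counts(
            {"spastic": 150, "rigid": 150, "hypotonic": 135, "normal": 150}
        )
        train, test = clf.split_dataset(df, SplitSpec(seed=0))
        assert len(train) == 468 and len(test) == 117
        # per-class rounding: round(0.8 * n) to train
        for cls, n in (("spastic", 150), ("hypotonic", 135)):
            assert (train["label"] == cls).sum() == round(0.8 * n)

    def test_same_seed_same_membership(self):
        df = table_with_counts({c: 20 for c in CLASS_ORDER})
        t1, e1 = clf.split_dataset(df, SplitSpec(seed=9))
        t2, e2 = clf.split_dataset(df, SplitSpec(seed=9))
        assert t1.equals(t2) and e1.equals(e2)

    def test_single_class_raises(self):
        df = table_with_counts({"normal": 10})
        with pytest.raises(ValueError):
            clf.split_dataset(df, SplitSpec())

    def test_subject_grouping_no_leakage(self):
        df = table_with_counts({c: 50 for c in CLASS_ORDER}, subjects_per_class=10)
        train, test = clf.split_dataset(df, SplitSpec(seed=3, grouping="subject"))
        assert set(train.index).isdisjoint(set(test.index))
        assert len(train) + len(test) == len(df)


class TestTrainModel:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_separable_clusters_reach_perfect_cv(self, kind):
        df = make_toy_table(n_per_class=10, separation=8.0, noise=0.3, seed=1)
        small = {
            "knn": {"model__n_neighbors": [3]},
            "svm": {"model__C": [1.0, 10.0]},
            "rf": {"model__n_estimators": [100]},
            "gbm": {"model__n_estimators": [50], "model__max_depth": [2]},
        }
        r = clf.train_model(kind, df, SplitSpec(seed=0), small[kind])
        assert r.cv_accuracy == pytest.approx(1.0)

    def test_unknown_kind(self):
        df = make_toy_table()
        with pytest.raises(ValueError):
            clf.train_model("mlp", df, SplitSpec())

    def test_deterministic_selection(self):
        df = make_toy_table(n_per_class=12, separation=2.0, noise=1.0, seed=5)
        grid = {"model__n_neighbors": [1, 3, 5, 7], "model__weights": ["uniform", "distance"]}
        r1 = clf.train_model("knn", df, SplitSpec(seed=4), grid)
        r2 = clf.train_model("knn", df, SplitSpec(seed=4), grid)
        assert r1.best_params == r2.best_params
        assert r1.cv_accuracy == r2.cv_accuracy


class _FixedPredictor:
    def __init__(self, predictions):
        self._p = np.asarray(predictions)

    def predict(self, X):
        return self._p[: len(X)]


def _result_with(predictions):
    return ModelResult(kind="knn", estimator=_FixedPredictor(predictions),
                       best_params={}, cv_accuracy=1.0)


class TestEvaluate:
    def _balanced_test(self, n_per_class=5):
        df = make_toy_table(n_per_class=n_per_class, seed=2)
        return df

    def test_perfect_predictions(self):
        df = self._balanced_test()
        r = clf.evaluate_model(_result_with(df["label"].to_numpy()), df)
        assert r.accuracy == r.precision == r.recall == r.f1 == 1.0
        np.testing.assert_allclose(np.diag(r.confusion_percent), 100.0)

    def test_constant_classifier_on_balanced_data(self):
        df = self._balanced_test()
        r = clf.evaluate_model(_result_with(["normal"] * len(df)), df)
        assert r.accuracy == pytest.approx(0.25)
        assert r.recall == pytest.approx(0.25)

    def test_f1_matches_confusion_count_oracle(self):
        rng = np.random.default_rng(8)
        df = self._balanced_test(n_per_class=12)
        noisy = rng.choice(list(CLASS_ORDER), size=len(df))
        # keep all classes predicted at least once deterministically
        r = clf.evaluate_model(_result_with(noisy), df)
        counts = r.confusion_counts
        f1s = []
        for i in range(4):
            tp = counts[i, i]
            prec = tp / counts[:, i].sum() if counts[:, i].sum() else 0.0
            rec = tp / counts[i, :].sum()
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert r.f1 == pytest.approx(np.mean(f1s), abs=1e-9)
        assert r.accuracy == pytest.approx(np.trace(counts) / counts.sum(), abs=1e-12)

    def test_missing_class_in_test_raises(self):
        df = self._balanced_test()
        df = df[df["label"] != "rigid"]
        with pytest.raises(ValueError):
            clf.evaluate_model(_result_with(df["label"].to_numpy()), df)

    def test_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(3)
        df = self._balanced_test(n_per_class=9)
        r = clf.evaluate_model(_result_with(rng.choice(list(CLASS_ORDER), len(df))), df)
        np.testing.assert_allclose(r.confusion_percent.sum(axis=1), 100.0, atol=0.1)


class TestImportance:
    def test_single_informative_column_dominates(self):
        rng = np.random.default_rng(0)
        n = 40
        # constant (uninformative) columns: permutation cannot change them
        df = pd.DataFrame(
            np.zeros((n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
        )
        labels = np.repeat(list(CLASS_ORDER), n // 4)
        df[FEATURE_COLUMNS[0]] = pd.factorize(labels)[0] * 5.0 + rng.normal(0, 0.1, n)
        df["label"] = labels
        df.index = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
        r = clf.train_model("knn", df, SplitSpec(seed=0), {"model__n_neighbors": [3]})
        r = clf.evaluate_model(r, df)
        cols, feats, muscles = clf.feature_importance(r, df, n_permutations=10, seed=0)
        assert cols[FEATURE_COLUMNS[0]] > 90.0
        assert sum(cols.values()) == pytest.approx(100.0, abs=0.1)
        assert sum(feats.values()) == pytest.approx(100.0, abs=0.1)
        assert sum(muscles.values()) == pytest.approx(100.0, abs=0.1)


class TestRunStudy:
    def test_report_schema_and_determinism(self):
        df = make_toy_table(n_per_class=15, separation=6.0, noise=1.0, seed=6)
        grids = {
            "knn": {"model__n_neighbors": [3, 5]},
            "svm": {"model__C": [1.0]},
            "rf": {"model__n_estimators": [50]},
            "gbm": {"model__n_estimators": [30], "model__max_depth": [2]},
        }
        spec = SplitSpec(seed=2, cv_folds=5)
        rep1 = clf.run_study(df, spec, grids)
        rep2 = clf.run_study(df, spec, grids)
        assert set(rep1.models) == set(MODEL_KINDS)
        for kind in MODEL_KINDS:
            m1, m2 = rep1.models[kind], rep2.models[kind]
            assert 0.0 <= m1.accuracy <= 1.0
            assert m1.accuracy == m2.accuracy
            assert m1.confusion_percent.shape == (4, 4)
        assert rep1.ranking == rep2.ranking
        assert rep1.to_dict()["models"].keys() == rep2.to_dict()["models"].keys()
        assert rep1.best_model == rep1.ranking[0]
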