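"""Metrics arithmetic, subject-level splits and classifier evaluation."""

import numpy as np
import pandas as pd
import pytest

from vmstress import (
    ClassifierConfig,
    SplitConfig,
    SubsetSpec,
    confusion_metrics,
    evaluate,
    kappa,
    kappa_from_confusion,
    split,
)
from vmstress.classify import _fit_predict


class TestConfusionMetrics:
    def test_hand_computed_values(self):
        m = confusion_metrics(tp=50, tn=40, fp=5, fn=5)
        assert m["sensitivity"] == pytest.approx(100 * 50 / 55)
        assert m["specificity"] == pytest.approx(100 * 40 / 45)
        assert m["accuracy"] == pytest.approx(90.0)
        assert m["f1"] == pytest.approx(50 / 55)
        assert m["flags"] == []

    def test_perfect_classifier(self):
        m = confusion_metrics(tp=10, tn=10, fp=0, fn=0)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (100, 100, 100)
        assert m["f1"] == 1.0

    def test_all_positives_missed(self):
        m = confusion_metrics(tp=0, tn=10, fp=0, fn=10)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 100.0
        assert m["accuracy"] == 50.0
        assert m["f1"] == 0.0

    def test_undefined_rates_flagged_not_zeroed(self):
        m = confusion_metrics(tp=0, tn=5, fp=0, fn=0)
        assert m["sensitivity"] is None
        assert any("sensitivity" in f for f in m["flags"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 0)


class TestKappa:
    def test_arithmetic(self):
        assert kappa(0.9, 0.5) == pytest.approx(0.8)
        assert kappa(0.5, 0.5) == 0.0
        assert kappa(1.0, 0.5) == 1.0

    def test_undefined_when_chance_is_certain(self):
        with pytest.raises(ValueError):
            kappa(1.0, 1.0)

    def test_from_confusion_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 200)
        y_pred = np.where(rng.random(200) < 0.8, y_true, 1 - y_true)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        assert kappa_from_confusion(tp, tn, fp, fn) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12
        )


def _subject_table(n_g, n_b, seed=0, sep=0.0, channels=("EEG Fp1", "EEG T3"),
                   trials=("baseline", "task"), modes=range(1, 9)):
    """Feature table with a controllable class separation in 'area'."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_g + n_b):
        lab = "G" if i < n_g else "B"
        mu = sep if lab == "B" else 0.0
        for trial in trials:
            for ch in channels:
                for mode in modes:
                    rows.append({
                        "subject_id": f"s{i:03d}", "trial": trial,
                        "channel": ch, "mode": mode,
                        "area": rng.normal(mu, 1.0),
                        "m": rng.normal(mu, 1.0),
                        "ctm": rng.uniform(0, 1),
                        "label": lab,
                    })
    return pd.DataFrame(rows)


class TestSplit:
    def test_percentage_sizes_360(self):
        table = _subject_table(180, 180, channels=("EEG Fp1",),
                               trials=("task",), modes=[1])
        train, val, test = split(table, SplitConfig(mode="percentage", seed=0))
        assert (len(train), len(val), len(test)) == (252, 36, 72)
        assert not (set(train) & set(val) | set(train) & set(test)
                    | set(val) & set(test))

    def test_kfold_sizes_40(self):
        table = _subject_table(20, 20, channels=("EEG Fp1",),
                               trials=("task",), modes=[1])
        folds = split(table, SplitConfig(mode="kfold", k=10, seed=0))
        assert len(folds) == 10
        assert all(len(te) == 4 for _, te in folds)
        all_test = np.concatenate([te for _, te in folds])
        assert len(all_test) == 40 and len(set(all_test)) == 40

    def test_seed_determinism(self):
        table = _subject_table(12, 8)
        cfg = SplitConfig(mode="percentage", seed=9)
        a, b = split(table, cfg), split(table, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_kfold_requires_enough_subjects_per_class(self):
        table = _subject_table(12, 4)
        with pytest.raises(ValueError, match="k-fold"):
            split(table, SplitConfig(mode="kfold", k=10))

    def test_stratification_preserves_class_ratio(self):
        table = _subject_table(30, 10, channels=("EEG Fp1",),
                               trials=("task",), modes=[1])
        train, val, test = split(table, SplitConfig(mode="percentage", seed=3))
        lab = table.drop_duplicates("subject_id").set_index("subject_id")["label"]
        assert (lab.loc[test] == "B").sum() == 2   # 10 B * 20%


class TestEvaluate:
    def test_separable_classes_reach_ceiling(self):
        table = _subject_table(12, 12, seed=1, sep=6.0)
        rep = evaluate(table, SubsetSpec(), ClassifierConfig(kind="mlp", seed=0),
                       SplitConfig(mode="kfold", k=6, seed=0))
        assert rep.accuracy >= 99.0
        assert rep.tp + rep.tn + rep.fp + rep.fn == 48   # pooled = all instances

    def test_null_classes_near_chance(self):
        table = _subject_table(12, 12, seed=2, sep=0.0)
        rep = evaluate(table, SubsetSpec(), ClassifierConfig(kind="mlp", seed=0),
                       SplitConfig(mode="kfold", k=6, seed=0))
        # binomial 95% interval around 50% for n=48
        assert 35.0 <= rep.accuracy <= 65.0

    def test_svm_runs_and_reports(self):
        table = _subject_table(12, 12, seed=3, sep=6.0)
        rep = evaluate(table, SubsetSpec(), ClassifierConfig(kind="svm", seed=0),
                       SplitConfig(mode="kfold", k=6, seed=0))
        assert rep.classifier == "svm"
        assert 0 <= rep.accuracy <= 100
        assert -1 <= rep.kappa <= 1

    def test_percentage_mode_reports_validation_accuracy(self):
        table = _subject_table(20, 20, seed=4, sep=6.0)
        rep = evaluate(table, SubsetSpec(), ClassifierConfig(kind="mlp", seed=0),
                       SplitConfig(mode="percentage", seed=0))
        assert rep.validation_accuracy is not None
        assert rep.n_instances == rep.tp + rep.tn + rep.fp + rep.fn

    def test_seed_determinism(self):
        table = _subject_table(10, 10, seed=5, sep=2.0)
        args = (table, SubsetSpec(), ClassifierConfig(kind="mlp", seed=3),
                SplitConfig(mode="kfold", k=5, seed=3))
        assert evaluate(*args).to_dict() == evaluate(*args).to_dict()

    def test_duplicating_instances_leaves_metrics_unchanged(self):
        table = _subject_table(10, 10, seed=6, sep=4.0)
        doubled = pd.concat([table, table], ignore_index=True)
        args = lambda t: (t, SubsetSpec(), ClassifierConfig(kind="mlp", seed=1),
                          SplitConfig(mode="kfold", k=5, seed=1))
        assert evaluate(*args(table)).to_dict() == evaluate(*args(doubled)).to_dict()

    def test_region_subsetting_limits_features(self):
        table = _subject_table(8, 8, seed=7, sep=4.0)
        rep = evaluate(table, SubsetSpec(region="temporal", mode_group="m1_4"),
                       ClassifierConfig(kind="mlp", seed=0),
                       SplitConfig(mode="kfold", k=4, seed=0))
        assert rep.tp + rep.tn + rep.fp + rep.fn == 32

    def test_empty_subset_rejected(self):
        table = _subject_table(4, 4, channels=("EEG Fp1",))
        with pytest.raises(ValueError, match="empty subset"):
            evaluate(table, SubsetSpec(region="occipital"),
                     ClassifierConfig(), SplitConfig(mode="kfold", k=2))

    def test_gender_comparison_filters_subjects(self):
        table = _subject_table(8, 8, seed=8, sep=4.0)
        genders = {f"s{i:03d}": ("F" if i % 2 == 0 else "M") for i in range(16)}
        rep = evaluate(table, SubsetSpec(comparison="good_vs_bad_female"),
                       ClassifierConfig(kind="mlp", seed=0),
                       SplitConfig(mode="kfold", k=4, seed=0),
                       genders=genders)
        assert rep.tp + rep.tn + rep.fp + rep.fn == 16  # 8 subjects x 2 trials


def test_scaler_never_sees_test_data():
    """Training statistics alone define the standardization: a huge planted
    outlier in the test block must not move the fitted scaler."""
    rng = np.random.default_rng(0)
    X_tr = rng.normal(0, 1, (30, 4))
    y_tr = np.r_[np.zeros(15), np.ones(15)].astype(int)
    X_te = rng.normal(0, 1, (10, 4))
    X_te[0] = 1e6
    flags = []
    _, scaler, _ = _fit_predict(X_tr, y_tr, X_te, ClassifierConfig(kind="svm"), flags)
    np.testing.assert_allclose(scaler.mean_, X_tr.mean(axis=0), atol=1e-12)
    np.testing.assert_allclose(scaler.scale_, X_tr.std(axis=0), atol=1e-12)
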