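"""Cross-validation machinery: splits, leakage, metrics, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mfoct
from mfoct import (
    ClassifierBenchmark,
    ClassifierSpec,
    ConfusionCounts,
    aggregate,
    compute_metrics,
    evaluate_fold,
    normalize_features,
    sample_feature_table,
    stratified_kfold,
    train_classifier,
)
from mfoct.evaluation import CLASSIFIER_NAMES, validate_feature_table
from mfoct.multifractal import FEATURE_NAMES


def _table(n_per_class=20, seed=0, separation=None):
    if separation is None:
        return sample_feature_table(n_per_class=n_per_class, seed=seed)
    dist = mfoct.FeatureDistribution.table_defaults()
    if separation == 0:
        pooled = (dist.means["DR"] + dist.means["Normal"]) / 2.0
        dist.means["DR"] = pooled.copy()
        dist.means["Normal"] = pooled.copy()
    return sample_feature_table(dist, n_per_class=n_per_class, seed=seed)


class TestNormalization:
    def test_zscore_uses_train_statistics(self):
        train = _table(10, 0)
        test = _table(10, 99)
        train_n, test_n, params = normalize_features(train, test)
        col = FEATURE_NAMES[1]
        mu, sd = params["mean"][col], params["sd"][col]
        np.testing.assert_allclose(test_n[col], (test[col] - mu) / sd)
        assert train_n[col].mean() == pytest.approx(0.0, abs=1e-9)

    def test_hand_example(self):
        cols = dict.fromkeys(FEATURE_NAMES, [10.0, 10.0])
        train = pd.DataFrame({"ID": [1, 2], **cols, "class": ["DR", "Normal"]})
        train[FEATURE_NAMES[0]] = [8.0, 12.0]  # mean 10, sd 2
        test = train.copy()
        test[FEATURE_NAMES[0]] = [12.0, 12.0]
        with pytest.warns(RuntimeWarning):  # other columns are constant
            _, test_n, _ = normalize_features(train, test)
        np.testing.assert_allclose(test_n[FEATURE_NAMES[0]], 1.0)

    def test_no_leakage_of_test_statistics(self):
        """Shifting the test split must not change its transform."""
        train = _table(10, 0)
        test = _table(10, 1)
        shifted = test.copy()
        shifted[list(FEATURE_NAMES)] += 100.0
        _, t1, _ = normalize_features(train, test)
        _, t2, _ = normalize_features(train, shifted)
        np.testing.assert_allclose(
            t2[list(FEATURE_NAMES)].to_numpy(),
            t1[list(FEATURE_NAMES)].to_numpy() + 100.0 / np.array(
                [max(s, 1e-300) for s in
                 train[list(FEATURE_NAMES)].std(ddof=0)]
            ),
        )

    def test_constant_feature_passed_through_with_warning(self):
        train = _table(10, 0).copy()
        train["Db"] = 1.999
        test = _table(5, 1)
        with pytest.warns(RuntimeWarning, match="constant"):
            train_n, _, params = normalize_features(train, test)
        np.testing.assert_allclose(train_n["Db"], 0.0, atol=1e-12)  # centered, not scaled
        assert "Db" in params["constant"]


class TestStratifiedKFold:
    def test_exact_stratification_when_divisible(self):
        table = _table(100, 0)
        folds = stratified_kfold(table, k=5, seed=42)
        lookup = table.set_index("ID")["class"]
        for _, test_ids in folds:
            labels = lookup.loc[test_ids]
            assert (labels == "DR").sum() == 20
            assert (labels == "Normal").sum() == 20

    def test_folds_partition_all_rows(self):
        table = _table(13, 3)
        folds = stratified_kfold(table, k=5, seed=0)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == sorted(table["ID"])
        for train_ids, test_ids in folds:
            assert not set(train_ids) & set(test_ids)

    def test_seeded_determinism(self):
        table = _table(20, 1)
        f1 = stratified_kfold(table, k=5, seed=7)
        f2 = stratified_kfold(table, k=5, seed=7)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(_table(3, 0), k=5, seed=0)


class TestMetrics:
    def test_hand_computed_confusion(self):
        m = compute_metrics(ConfusionCounts(TP=90, TN=80, FP=20, FN=10))
        assert m["recall"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.80)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(90 / 110)
        p, r = 90 / 110, 0.9
        assert m["f1"] == pytest.approx(2 * p * r / (p + r))

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=20, TN=20, FP=0, FN=0))
        assert all(v == 1.0 for v in m.values())

    def test_undefined_precision_is_nan_not_zero(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            m = compute_metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=5))
        assert np.isnan(m["precision"])
        assert m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tp=st.integers(1, 50), tn=st.integers(1, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_f1_harmonic_mean_identity_and_bounds(self, tp, tn, fp, fn):
        m = compute_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        for v in m.values():
            assert 0.0 <= v <= 1.0
        assert m["f1"] == pytest.approx(
            2 * tp / (2 * tp + fp + fn)  # equivalent closed form
        )


class TestAggregate:
    def test_identical_folds_zero_width_ci(self):
        folds = [dict(accuracy=0.9, precision=0.9, recall=0.9, f1=0.9, specificity=0.9)] * 5
        rep = aggregate(folds)
        assert rep.mean_metrics["accuracy"] == 0.9
        assert rep.accuracy_ci95 == (0.9, 0.9)
        assert rep.p_value_vs_chance == 0.0

    def test_mean_is_arithmetic_mean(self):
        accs = [0.8950, 0.9142, 0.8842, 0.8983, 0.8942]
        folds = [dict(accuracy=a, precision=a, recall=a, f1=a, specificity=a) for a in accs]
        rep = aggregate(folds)
        assert rep.mean_metrics["accuracy"] == pytest.approx(np.mean(accs), abs=1e-12)
        lo, hi = rep.accuracy_ci95
        assert lo <= rep.mean_metrics["accuracy"] <= hi
        assert rep.p_value_vs_chance < 0.05

    def test_chance_level_not_significant(self):
        folds = [dict(accuracy=0.5, precision=0.5, recall=0.5, f1=0.5, specificity=0.5)] * 5
        assert aggregate(folds).p_value_vs_chance > 0.05

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate([dict(accuracy=1.0, precision=1, recall=1, f1=1, specificity=1)])


class TestClassifiers:
    def test_presets_mirror_published_configuration(self):
        mlp = ClassifierSpec("mlp").resolved()
        assert mlp["hidden_layer_sizes"] == (128, 64)
        assert mlp["activation"] == "relu"
        assert mlp["solver"] == "adam"
        assert mlp["max_iter"] == 1000
        assert mlp["random_state"] == 42
        assert ClassifierSpec("decision_tree").resolved() == {"max_depth": 5, "criterion": "entropy"}
        assert ClassifierSpec("svm_poly").resolved()["degree"] == 3
        assert ClassifierSpec("random_forest").resolved()["max_depth"] == 10
        assert len(CLASSIFIER_NAMES) == 8

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("resnet")

    def test_separable_data_learned_perfectly(self):
        table = _table(20, 0)
        # make the classes linearly separable on one feature
        table.loc[table["class"] == "DR", "spectrum_width"] = 2.0
        table.loc[table["class"] == "Normal", "spectrum_width"] = 0.5
        train_n, _, _ = normalize_features(table, table)
        for name in ("mlp", "svm_poly"):
            model = train_classifier(ClassifierSpec(name), train_n)
            counts = evaluate_fold(model, train_n)
            assert counts.FP == 0 and counts.FN == 0

    def test_mlp_uses_relu_hidden_and_sigmoid_output(self):
        train_n, _, _ = normalize_features(_table(10, 0), _table(2, 1))
        model = train_classifier(ClassifierSpec("mlp"), train_n)
        assert model.activation == "relu"
        assert model.out_activation_ == "logistic"  # sigmoid probability output
        proba = model.predict_proba(train_n[list(FEATURE_NAMES)].to_numpy())
        assert np.all((proba > 0) & (proba < 1))

    def test_degenerate_always_positive_predictor_counts(self):
        class AlwaysDR:
            def predict(self, x):
                return np.ones(len(x), dtype=int)

        test = _table(10, 2)
        counts = evaluate_fold(AlwaysDR(), test)
        assert counts.FN == 0 and counts.TN == 0
        assert counts.total == len(test)


class TestBenchmark:
    def test_benchmark_reports_structure(self):
        res = ClassifierBenchmark(_table(25, 0), models=["logistic_regression", "mlp"], seed=42).fit()
        df = res.fold_table()
        assert len(df) == 2 * (5 + 1)  # folds + average per model
        assert set(res.reports) == {"logistic_regression", "mlp"}
        for rep in res.reports.values():
            for c in rep.fold_confusions:
                assert c.total == 10  # 50 rows / 5 folds
        text = res.summary()
        assert "mlp" in text and "acc" in text

    def test_zero_separation_runs_at_chance(self):
        res = ClassifierBenchmark(
            _table(40, 3, separation=0), models="all", k=5, seed=42
        ).fit()
        df = res.fold_table()
        assert len(df) == 8 * 6
        for rep in res.reports.values():
            assert 0.4 <= rep.mean_metrics["accuracy"] <= 0.6, rep.model_name

    def test_seeded_end_to_end_determinism(self):
        t = _table(20, 4)
        r1 = ClassifierBenchmark(t, models=["mlp"], seed=42).fit()
        r2 = ClassifierBenchmark(t, models=["mlp"], seed=42).fit()
        assert r1.reports["mlp"].to_dict() == r2.reports["mlp"].to_dict()

    def test_saved_reports(self, tmp_path):
        res = ClassifierBenchmark(_table(15, 5), models=["decision_tree"], seed=1).fit()
        res.save(tmp_path)
        for name in ("report.json", "table6.csv", "table7.csv", "confusion.json"):
            assert (tmp_path / name).exists()


class TestFeatureTableValidation:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            validate_feature_table(pd.DataFrame({"ID": [1]}))

    def test_missing_values_rejected(self):
        t = _table(5, 0)
        t.loc[0, "Db"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            validate_feature_table(t)

    def test_csv_parse_error_mentions_file(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text('ID,Db\n1,"unterminated\n')
        with pytest.raises(ValueError):
            mfoct.load_feature_table(bad)
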