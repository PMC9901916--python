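"""Classifier configs, metric identities, CV schemes and transfer."""

import warnings

import numpy as np
import pytest

from braggveto.classify import (
    GNBConfig,
    HitMissPipeline,
    MLPConfig,
    RFConfig,
    SVMConfig,
    confusion_matrix,
    cross_dataset_matrix,
    cross_validate,
    evaluate,
    evaluate_predictions,
    make_classifier,
    metrics_from_counts,
    train,
)
from braggveto.simulator import HIT, MISS


from hypothesis import given, settings
from hypothesis import strategies as st


def _labels_from_counts(tp, fp, fn, tn):
    y_true = [HIT] * (tp + fn) + [MISS] * (fp + tn)
    y_pred = [HIT] * tp + [MISS] * fn + [HIT] * fp + [MISS] * tn
    return y_true, y_pred


class TestMetrics:
    def test_fixed_confusion_counts_closed_form(self):
        # TP=50 FP=10 FN=10 TN=30: precision = recall = F1 = 83.33%,
        # accuracy = 80.00%
        m = metrics_from_counts(tp=50, fp=10, fn=10, tn=30)
        assert m["precision"] == pytest.approx(83.3333, abs=1e-3)
        assert m["recall"] == pytest.approx(83.3333, abs=1e-3)
        assert m["f1"] == pytest.approx(83.3333, abs=1e-3)
        assert m["accuracy"] == pytest.approx(80.0)

    def test_report_identities_hold_exactly(self):
        y_true, y_pred = _labels_from_counts(50, 10, 10, 30)
        r = evaluate_predictions(y_true, y_pred)
        assert (r.tp, r.fp, r.fn, r.tn) == (50, 10, 10, 30)
        m = metrics_from_counts(r.tp, r.fp, r.fn, r.tn)
        assert r.precision == m["precision"]
        assert r.f1 == m["f1"]
        assert r.tp + r.fp + r.fn + r.tn == len(y_true)

    def test_perfect_predictions_all_100(self):
        y = [HIT] * 5 + [MISS] * 5
        r = evaluate_predictions(y, y)
        assert (r.precision, r.recall, r.f1, r.accuracy) == (100.0, 100.0, 100.0, 100.0)

    def test_all_miss_on_balanced_data(self):
        y_true = [HIT] * 10 + [MISS] * 10
        r = evaluate_predictions(y_true, [MISS] * 20)
        assert r.accuracy == 50.0
        assert r.recall == 0.0
        assert r.precision == 0.0
        assert r.precision_undefined

    @settings(derandomize=True, max_examples=50)
    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        fn=st.integers(0, 40), tn=st.integers(1, 40),
    )
    def test_metric_identities_hold_for_any_counts(self, tp, fp, fn, tn):
        m = metrics_from_counts(tp, fp, fn, tn)
        assert m["accuracy"] == pytest.approx(100 * (tp + tn) / (tp + fp + fn + tn))
        for v in m.values():
            assert 0.0 <= v <= 100.0
        if m["precision"] and m["recall"]:
            hm = 2 / (100 / m["precision"] + 100 / m["recall"])
            assert m["f1"] == pytest.approx(100 * hm)

    @pytest.mark.parametrize("tp,fp,fn,tn", [(3, 1, 2, 4), (7, 0, 0, 3), (1, 5, 5, 1)])
    def test_metric_formulas_recomputed_from_confusion(self, tp, fp, fn, tn):
        y_true, y_pred = _labels_from_counts(tp, fp, fn, tn)
        r = evaluate_predictions(y_true, y_pred)
        assert r.accuracy == pytest.approx(100 * (tp + tn) / (tp + fp + fn + tn))
        if tp + fp:
            assert r.precision == pytest.approx(100 * tp / (tp + fp))
        if tp + fn:
            assert r.recall == pytest.approx(100 * tp / (tp + fn))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.1, (40, 10)), rng.normal(1, 0.1, (40, 10))])
    y = np.array([HIT] * 40 + [MISS] * 40)
    return X, y


class TestTrain:

    def test_single_class_training_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="single class"):
            train(X, [HIT] * 10, SVMConfig())

    def test_svm_separable_training_accuracy_100(self, separable):
        X, y = separable
        clf = train(X, y, SVMConfig(C=10.0))
        assert evaluate(clf, X, y).accuracy == 100.0

    def test_seeded_determinism(self, separable):
        X, y = separable
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = train(X, y, MLPConfig(seed=4, max_epochs=50)).predict(X)
            p2 = train(X, y, MLPConfig(seed=4, max_epochs=50)).predict(X)
        assert (p1 == p2).all()

    def test_mlp_input_width_equals_codebook_size(self, separable):
        X, y = separable
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = train(X, y, MLPConfig(max_epochs=20))
        assert clf.coefs_[0].shape[0] == X.shape[1]
        assert [c.shape[1] for c in clf.coefs_[:-1]] == [50, 30, 20, 20, 20, 30, 50]

    def test_configured_hyperparameters_reach_sklearn(self):
        assert make_classifier(SVMConfig()).gamma == 0.001
        assert make_classifier(RFConfig()).n_estimators == 100
        assert make_classifier(RFConfig()).criterion == "gini"
        mlp = make_classifier(MLPConfig())
        assert mlp.alpha == 1e-5
        assert mlp.activation == "relu"
        assert mlp.solver == "sgd"
        assert make_classifier("nb").var_smoothing == GNBConfig().var_smoothing


class TestCrossValidation:
    def test_folds_partition_dataset(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([HIT] * 20 + [MISS] * 20)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.concatenate([te for _, te in skf.split(np.zeros(40), y)])
        assert sorted(seen) == list(range(40))

    def test_small_class_rejected(self):
        X = np.random.default_rng(1).normal(size=(8, 4))
        y = np.array([HIT] * 3 + [MISS] * 5)
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(X, y, model="nb", k_folds=5)

    def test_pipeline_cv_on_simulated_descriptors(self, small_descriptors):
        descriptors, counts, labels = small_descriptors
        cv = cross_validate(descriptors, labels, model="rf", random_state=0)
        assert cv["accuracy_mean"] >= 90.0
        assert cv["n_folds"] == 5
        assert len(cv["reports"]) == 5

    def test_permutation_null_is_at_chance(self, null_features):
        # permuted labels must give chance-level accuracy on balanced data
        X, labels = null_features
        rng = np.random.default_rng(123)
        means = []
        for _ in range(20):
            perm = rng.permutation(len(labels))
            cv = cross_validate(X, labels[perm], model="nb", random_state=0)
            means.append(cv["accuracy_mean"])
        assert abs(np.mean(means) - 50.0) <= 3.0


class TestCrossDataset:
    def test_domain_gap_off_diagonal_not_above_diagonal(self, small_descriptors):
        from braggveto import OrbFeatureExtractor, SimConfig, generate_dataset

        descriptors, counts, labels = small_descriptors
        shifted_cfg = SimConfig(
            n_hit=30, n_miss=30, seed=55,
            background_level=1200.0, peak_amplitude=(1500.0, 6000.0),
        )
        shifted = generate_dataset(shifted_cfg)
        ext = OrbFeatureExtractor().fit()
        descB = ext.transform(shifted)
        yB = np.array([f.truth_label for f in shifted])
        mat = cross_dataset_matrix(
            {"A": (descriptors, labels), "B": (descB, yB)}, model="rf", random_state=0
        )
        assert mat.loc["A", "B"] <= mat.loc["A", "A"]
        assert mat.loc["B", "A"] <= mat.loc["B", "B"]
        # matrix need not be symmetric
        assert mat.shape == (2, 2)

    def test_feature_dimension_mismatch_detected(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (10, 10)), rng.normal(3, 1, (10, 10))])
        y = np.array([HIT] * 10 + [MISS] * 10)
        clf = train(X, y, RFConfig())
        with pytest.raises(ValueError):
            clf.predict(rng.normal(size=(4, 7)))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.1, (20, 5)), rng.normal(5, 0.1, (20, 5))])
        y = np.array([HIT] * 20 + [MISS] * 20)
        clf = train(X, y, RFConfig())
        cm, classes = confusion_matrix(clf, X, y)
        assert cm.sum() == 40
        assert np.trace(cm) == 40
        assert classes[0] == HIT  # hit is the positive class
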