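import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import accuracy_score, matthews_corrcoef

from sumoacet.ifs import (
    ClassifierSpec,
    ConfusionCounts,
    compute_metrics,
    foldsafe_ifs_curve,
    ifs_curve,
    jackknife_evaluate,
    train_classifier,
)


def _vectors_from_counts(cc: ConfusionCounts):
    y_true = [1] * cc.TP + [1] * cc.FN + [0] * cc.TN + [0] * cc.FP
    y_pred = [1] * cc.TP + [0] * cc.FN + [0] * cc.TN + [1] * cc.FP
    return np.array(y_true), np.array(y_pred)


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.mcc) == (1, 1, 1, 1)

    def test_majority_class_baseline(self):
        """Predicting every sample as acetylation on a 218/926 dataset gives
        80.94% accuracy and, with a zero denominator, MCC = 0."""
        m = compute_metrics(ConfusionCounts(TP=0, TN=926, FP=0, FN=218))
        assert round(100 * m.accuracy, 2) == 80.94
        assert m.mcc == 0.0

    def test_agrees_with_sklearn_on_reconstructed_counts(self):
        """The confusion matrix implied by SN=71.10% of 218 positives and
        SP=97.09% of 927 negatives yields ACC 92.14% and MCC 0.7322."""
        tp = round(0.7110 * 218)
        tn = round(0.9709 * 927)
        cc = ConfusionCounts(TP=tp, TN=tn, FP=927 - tn, FN=218 - tp)
        m = compute_metrics(cc)
        y_true, y_pred = _vectors_from_counts(cc)
        assert m.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))
        assert round(100 * m.accuracy, 2) == 92.14
        assert round(m.mcc, 4) == 0.7322

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(ValueError, match="sensitivity"):
            compute_metrics(ConfusionCounts(TP=0, TN=5, FP=5, FN=0))
        with pytest.raises(ValueError, match="specificity"):
            compute_metrics(ConfusionCounts(TP=5, TN=0, FP=0, FN=5))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 500), tn=st.integers(0, 500),
        fp=st.integers(0, 500), fn=st.integers(0, 500),
    )
    def test_metric_identities(self, tp, tn, fp, fn):
        """ACC = (SN*n_pos + SP*n_neg)/n; MCC in [-1,1]; swapping the class
        labels swaps SN and SP and leaves ACC and MCC unchanged."""
        if tp + fn == 0 or tn + fp == 0:
            return
        cc = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
        m = compute_metrics(cc)
        n_pos, n_neg = tp + fn, tn + fp
        assert m.accuracy == pytest.approx(
            (m.sensitivity * n_pos + m.specificity * n_neg) / (n_pos + n_neg)
        )
        assert -1 <= m.mcc <= 1
        swapped = compute_metrics(ConfusionCounts(TP=tn, TN=tp, FP=fn, FN=fp))
        assert swapped.sensitivity == pytest.approx(m.specificity)
        assert swapped.specificity == pytest.approx(m.sensitivity)
        assert swapped.accuracy == pytest.approx(m.accuracy)
        assert swapped.mcc == pytest.approx(m.mcc)


class TestClassifier:
    def test_memorizes_label_feature(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=30)
        X = np.column_stack([y.astype(float), rng.normal(size=30)])
        clf = train_classifier(X, y, seed=0)
        assert accuracy_score(y, clf.predict(X)) == 1.0

    def test_deterministic_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, size=40)
        p1 = train_classifier(X, y, seed=3).predict(X)
        p2 = train_classifier(X, y, seed=3).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((4, 2)), np.zeros(4), seed=0)

    def test_larger_ensemble_not_worse_on_average(self):
        """On noisy planted-signal data the 100-tree forest's mean jackknife
        MCC over repeated draws is at least the single tree's."""
        def mean_mcc(n_trees):
            vals = []
            for seed in range(6):
                rng = np.random.default_rng(100 + seed)
                y = np.repeat([0, 1], 20)
                X = rng.normal(size=(40, 10))
                X[:, 0] += 0.9 * y
                X[:, 1] += 0.9 * y
                cc = jackknife_evaluate(
                    X, y, ClassifierSpec(n_trees=n_trees), seed=seed
                )
                vals.append(compute_metrics(cc).mcc)
            return np.mean(vals)

        assert mean_mcc(100) >= mean_mcc(1)


class TestJackknife:
    def test_separated_clusters_classified(self):
        """Two Gaussian clusters 4 sd apart (Bayes error < 1%) give
        leave-one-out accuracy of at least 0.95."""
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 1)) + 4.0 * y[:, None]
        cc = jackknife_evaluate(X, y, seed=0)
        m = compute_metrics(cc)
        assert m.accuracy >= 0.95
        assert cc.TP + cc.FN == 20  # accounting identity
        assert cc.total == 40

    def test_deterministic_counts(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(24, 4))
        y = np.tile([0, 1], 12)
        assert jackknife_evaluate(X, y, seed=5) == jackknife_evaluate(X, y, seed=5)

    def test_stratified_kfold_fallback(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 2)) + 3.0 * y[:, None]
        cc = jackknife_evaluate(X, y, seed=0, folds=5)
        assert compute_metrics(cc).accuracy >= 0.9


def _mrmr_like_table(p):
    return pd.DataFrame({"rank": np.arange(1, p + 1), "index": np.arange(p),
                         "block": "PSSM", "site": 1, "subtype": "A"})


class TestIFSCurve:
    def test_recovers_planted_features(self):
        """5 informative features among 50 noise: the MCC curve rises from
        k=1 and the optimal prefix contains at least 4 of the 5 planted."""
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 55))
        planted = [0, 1, 2, 3, 4]
        for j in planted:
            X[:, j] += 1.6 * y
        from sumoacet.mrmr import discretize_matrix, mrmr_rank

        table = mrmr_rank(discretize_matrix(X, y))
        res = ifs_curve(table, X, y, k_min=1, k_max=25, k_step=3, seed=0)
        records = res.records
        assert res.optimal_mcc > records["MCC"].iloc[0]
        assert res.optimal_mcc == records["MCC"].max()
        top = set(int(r) for r in res.optimal_features["index"])
        assert len(top & set(planted)) >= 4

    def test_single_k_grid(self):
        rng = np.random.default_rng(7)
        y = np.tile([0, 1], 10)
        X = rng.normal(size=(20, 3)) + 2.0 * y[:, None]
        res = ifs_curve(_mrmr_like_table(3), X, y, k_min=1, k_max=1, seed=0)
        assert len(res.records) == 1
        assert res.optimal_k == 1

    def test_prefixes_are_nested(self):
        rng = np.random.default_rng(8)
        y = np.tile([0, 1], 10)
        X = rng.normal(size=(20, 6)) + 1.5 * y[:, None]
        res = ifs_curve(_mrmr_like_table(6), X, y, k_max=6, seed=0)
        assert list(res.optimal_features["rank"]) == list(
            range(1, res.optimal_k + 1)
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ifs_curve(_mrmr_like_table(0), np.zeros((4, 2)), np.array([0, 1, 0, 1]))

    def test_foldsafe_variant_runs(self):
        rng = np.random.default_rng(9)
        y = np.tile([0, 1], 8)
        X = rng.normal(size=(16, 6))
        X[:, 0] += 2.0 * y
        records = foldsafe_ifs_curve(X, y, k_min=1, k_max=4, k_step=3, seed=0)
        assert list(records["k"]) == [1, 4]
        assert np.isfinite(records["MCC"]).all()
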