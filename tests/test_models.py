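"""Classifier and metric suite, checked against independent oracles."""

import math

import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from nvdt import models
from nvdt.models import (ConfusionCounts, ModelSpec, confusion, cross_validate,
                         evaluate, metrics, predict, train)
from nvdt.standardize import Standardizer

FAST_SPEC = ModelSpec(kind="SVM", svm_c=[1.0, 32.0], svm_gamma=[1 / 128, 1 / 8],
                      seed=0)


# -- independent metric oracle: plain-python arithmetic -----------------

def oracle_metrics(tp, fp, tn, fn):
    def div(a, b):
        return a / b if b else 0.0
    acc = div(tp + tn, tp + tn + fp + fn)
    pre = div(tp, tp + fp)
    sen = div(tp, tp + fn)
    spe = div(tn, tn + fp)
    den = math.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = div(tp * tn - fp * fn, den)
    f1 = div(2 * pre * sen, pre + sen)
    return acc, pre, sen, spe, mcc, f1


def mann_whitney_auc(y, s):
    pos = [x for x, t in zip(s, y) if t == 1]
    neg = [x for x, t in zip(s, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_worked_example(self):
        r = metrics(ConfusionCounts(tp=50, fp=10, tn=40, fn=5))
        assert r.acc == pytest.approx(90 / 105, rel=1e-9)
        assert r.pre == pytest.approx(50 / 60, rel=1e-9)
        assert r.sen == pytest.approx(50 / 55, rel=1e-9)
        assert r.mcc == pytest.approx(1950 / math.sqrt(55 * 50 * 60 * 45), rel=1e-9)
        assert r.mcc == pytest.approx(0.7156264, abs=1e-6)
        assert r.f1 == pytest.approx(0.869565, abs=1e-6)

    def test_symmetric_counts(self):
        r = metrics(ConfusionCounts(25, 25, 25, 25))
        assert r.mcc == 0.0 and r.acc == 0.5

    def test_oracle_equivalence_500_random_matrices(self, rng):
        for _ in range(500):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            cm = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            if cm.total == 0:
                continue
            r = metrics(cm)
            expect = oracle_metrics(*map(int, (tp, fp, tn, fn)))
            got = (r.acc, r.pre, r.sen, r.spe, r.mcc, r.f1)
            np.testing.assert_allclose(got, expect, rtol=1e-12, atol=1e-12)

    def test_mcc_agrees_with_sklearn(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=60)
            p = rng.integers(0, 2, size=60)
            if len(set(y)) < 2 or len(set(p)) < 2:
                continue
            r = metrics(confusion(y, p))
            assert r.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    def test_zero_denominators_flagged(self):
        r = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert r.pre == 0.0 and r.sen == 0.0
        assert {"pre", "sen", "mcc", "f1"} <= set(r.undefined)

    def test_perfectly_separated_scores_auc_one(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.2, 0.8, 0.9]
        r = metrics(confusion(y, [0, 0, 1, 1]), scores=s, y_true=y)
        assert r.auc == pytest.approx(1.0)

    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(30):
            y = rng.integers(0, 2, size=40)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.uniform(size=40), 1)  # coarse grid forces ties
            got = models.auc_trapezoid(y, s)
            assert got == pytest.approx(mann_whitney_auc(y, s), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestConfusion:
    def test_direct_count(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect(self):
        cm = confusion([1, 0], [1, 0])
        assert cm.fp == cm.fn == 0

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            confusion([], [])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            confusion([1], [1, 0])


def blobs(n=60, seed=0):
    X, y = make_blobs(n_samples=n, centers=[[-5.0, -5.0], [5.0, 5.0]],
                      cluster_std=1.0, random_state=seed)
    return X, y


class TestTrainPredict:
    def test_separable_blobs_perfect_training_accuracy(self):
        X, y = blobs()
        model = train(X, y, FAST_SPEC)
        labels, _ = predict(model, X)
        assert (labels == y).all()

    def test_determinism_of_hyperparameter_choice(self):
        X, y = blobs(seed=3)
        m1 = train(X, y, FAST_SPEC)
        m2 = train(X, y, FAST_SPEC)
        assert m1.best_params == m2.best_params

    def test_single_class_errors(self):
        X, _ = blobs()
        with pytest.raises(ValueError, match="both classes"):
            train(X, np.ones(len(X), dtype=int), FAST_SPEC)

    def test_rf_kind(self):
        X, y = blobs(seed=5)
        model = train(X, y, ModelSpec(kind="RF", rf_n_tree=[25], seed=0))
        assert "n_estimators" in model.best_params
        _, scores = predict(model, X)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_scores_in_unit_interval_and_cutoff(self):
        X, y = blobs(seed=2)
        model = train(X, y, FAST_SPEC)
        labels, scores = predict(model, X, cutoff=0.5)
        assert ((scores > 0) & (scores < 1)).all()
        np.testing.assert_array_equal(labels, (scores >= 0.5).astype(int))

    def test_cutoff_zero_like_all_positive(self):
        X, y = blobs(seed=2)
        model = train(X, y, FAST_SPEC)
        labels, _ = predict(model, X, cutoff=1e-12)
        assert labels.all()

    def test_dimension_mismatch(self):
        X, y = blobs()
        model = train(X, y, FAST_SPEC)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, X[:, :1])

    def test_standardizer_fitted_on_training_rows_only(self):
        X, y = blobs(seed=1)
        model = train(X, y, FAST_SPEC)
        np.testing.assert_allclose(model.standardizer.means, X.mean(axis=0),
                                   rtol=1e-12)
        assert model.standardizer.n_fit == len(X)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="cutoff"):
            ModelSpec(cutoff=0.0)
        with pytest.raises(ValueError, match="kind"):
            ModelSpec(kind="MLP")
        with pytest.raises(ValueError, match="non-empty"):
            ModelSpec(svm_c=[])


class TestCrossValidate:
    def test_fold_count_and_perfect_separation(self, small_dataset):
        seqs, prs = small_dataset
        res = cross_validate(seqs, prs, FAST_SPEC, k=5, seed=0)
        assert len(res.folds) == 5
        assert res.mean["acc"] == pytest.approx(1.0)
        assert res.std["acc"] == pytest.approx(0.0)

    def test_determinism(self, small_dataset):
        seqs, prs = small_dataset
        a = cross_validate(seqs, prs, FAST_SPEC, k=3, seed=2)
        b = cross_validate(seqs, prs, FAST_SPEC, k=3, seed=2)
        assert a.mean == b.mean and a.std == b.std

    def test_per_fold_standardizer_sees_only_training_rows(self, small_dataset,
                                                           monkeypatch):
        seqs, prs = small_dataset
        fit_sizes = []
        orig_fit = Standardizer.fit

        def spy(self, X, feature_names=None):
            fit_sizes.append(np.asarray(X).shape[0])
            return orig_fit(self, X, feature_names)

        monkeypatch.setattr(Standardizer, "fit", spy)
        cross_validate(seqs, prs, FAST_SPEC, k=5, seed=0)
        n = len(prs)
        assert fit_sizes == [n - n // 5] * 5

    def test_to_frame_layout(self, small_dataset):
        seqs, prs = small_dataset
        res = cross_validate(seqs, prs, FAST_SPEC, k=3, seed=0)
        df = res.to_frame()
        assert list(df.index) == ["fold1", "fold2", "fold3", "mean", "std"]
        assert list(df.columns) == ["acc", "pre", "sen", "spe", "mcc", "f1", "auc"]


def test_model_save_load_round_trip(tmp_path):
    X, y = blobs(seed=8)
    model = train(X, y, FAST_SPEC)
    path = tmp_path / "model.joblib"
    models.save_model(model, path)
    back = models.load_model(path)
    l1, s1 = predict(model, X)
    l2, s2 = predict(back, X)
    np.testing.assert_array_equal(l1, l2)
    np.testing.assert_allclose(s1, s2, rtol=1e-15)
    r = evaluate(back, X, y)
    assert r.acc == pytest.approx(1.0)
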