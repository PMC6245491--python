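"""Softmax classifier: probability algebra, training, evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from chromaim import SoftmaxClassifier, evaluate
from chromaim.softmax import softmax


def _model(W, b, classes):
    clf = SoftmaxClassifier()
    clf.coef_ = np.asarray(W, dtype=float)
    clf.intercept_ = np.asarray(b, dtype=float)
    clf.classes_ = np.asarray(classes)
    clf._hidden = None
    return clf


def test_zero_model_predicts_uniform():
    clf = _model(np.zeros((4, 3)), np.zeros(4), list("abcd"))
    p = clf.predict_proba(np.ones(3))
    assert np.allclose(p, 0.25)


def test_probabilities_on_simplex():
    rng = np.random.default_rng(0)
    clf = _model(rng.normal(size=(5, 4)) * 50, rng.normal(size=5) * 10, range(5))
    P = clf.predict_proba(rng.normal(size=(100, 4)) * 20)
    assert np.all(P >= 0)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)


def test_shift_invariance_of_softmax():
    rng = np.random.default_rng(1)
    z = rng.normal(size=(20, 6))
    assert np.allclose(softmax(z), softmax(z + 123.456), atol=1e-12)


def test_two_class_reduces_to_logistic_sigmoid():
    rng = np.random.default_rng(2)
    w = rng.normal(size=3)
    clf = _model(np.stack([w, -w]), np.array([0.5, -0.5]), [0, 1])
    X = rng.normal(size=(30, 3))
    margin = 2 * (X @ w) + 1.0  # z_0 - z_1
    assert np.allclose(clf.predict_proba(X)[:, 0], expit(margin), atol=1e-12)


def test_matches_printed_equations_directly():
    """predict_proba equals a naive exp/normalise evaluation of z, t, a."""
    rng = np.random.default_rng(3)
    W = rng.normal(size=(6, 4))
    b = rng.normal(size=6)
    X = rng.normal(size=(50, 4))
    clf = _model(W, b, range(6))
    z = X @ W.T + b
    naive = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    assert np.allclose(clf.predict_proba(X), naive, atol=1e-12)


def test_argmax_prediction_and_tie_break():
    clf = _model([[1.0], [0.5], [0.1]], [0, 0, 0], ["x", "y", "z"])
    assert clf.predict(np.array([[1.0]]))[0] == "x"
    tie = _model([[0.0], [0.0]], [0.0, 0.0], ["first", "second"])
    assert tie.predict(np.array([[3.0]]))[0] == "first"  # exact tie -> first class


def test_batch_equals_per_row_prediction():
    rng = np.random.default_rng(4)
    clf = _model(rng.normal(size=(3, 2)), rng.normal(size=3), list("abc"))
    X = rng.normal(size=(25, 2))
    batch = clf.predict(X)
    rows = [clf.predict(x[None, :])[0] for x in X]
    assert list(batch) == rows


def test_separable_two_class_fit_reaches_full_accuracy():
    X = np.array([[0.0], [0.1], [0.9], [1.0]])
    y = np.array([0, 0, 1, 1])
    clf = SoftmaxClassifier(epochs=2000).fit(X, y)
    assert (clf.predict(X) == y).all()


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(5)
    n, F, K = 12, 3, 4
    X = rng.normal(size=(n, F))
    Y = np.eye(K)[rng.integers(0, K, n)]
    w_sample = rng.uniform(0.5, 2.0, size=n)
    W = rng.normal(size=(K, F))
    b = rng.normal(size=K)
    loss, gW, gb = SoftmaxClassifier._loss_grad(W, b, X, Y, w_sample, l2=0.01)
    h = 1e-6
    for arr, grad in ((W, gW), (b, gb)):
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            lp = SoftmaxClassifier._loss_grad(W, b, X, Y, w_sample, 0.01)[0]
            arr[idx] = orig - h
            lm = SoftmaxClassifier._loss_grad(W, b, X, Y, w_sample, 0.01)[0]
            arr[idx] = orig
            fd = (lp - lm) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-6, abs=1e-8)


def test_two_class_fit_agrees_with_sklearn_logistic():
    """K=2 softmax regression is binary logistic regression."""
    rng = np.random.default_rng(6)
    n, l2 = 80, 1e-3
    X = rng.normal(size=(n, 2))
    y = (X @ [1.0, -0.7] + 0.3 * rng.normal(size=n) > 0).astype(int)
    ours = SoftmaxClassifier(learning_rate=0.5, epochs=30000, l2=l2).fit(X, y)
    # matched penalty: ours is mean CE + (l2/2)(|w0|^2+|w1|^2); on the margin
    # w1 - w0 that is (l2/4)|d|^2, i.e. sklearn C = 2 / (n * l2)
    sk = LogisticRegression(C=2 / (n * l2), tol=1e-10, max_iter=10000).fit(X, y)
    Xt = rng.normal(size=(40, 2))
    assert np.allclose(ours.predict_proba(Xt), sk.predict_proba(Xt), atol=5e-4)


def test_training_loss_nonincreasing():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(60, 3))
    y = rng.integers(0, 3, size=60)
    clf = SoftmaxClassifier(learning_rate=0.05, epochs=300).fit(X, y)
    assert np.all(np.diff(clf.loss_curve_) <= 1e-12)


def test_sample_weight_equals_data_duplication():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(10, 2))
    y = rng.integers(0, 2, size=10)
    dup = SoftmaxClassifier(epochs=200).fit(
        np.vstack([X, X[:3]]), np.concatenate([y, y[:3]])
    )
    w = np.ones(10)
    w[:3] = 2.0
    weighted = SoftmaxClassifier(epochs=200).fit(X, y, sample_weight=w)
    assert np.allclose(dup.coef_, weighted.coef_, atol=1e-10)
    assert np.allclose(dup.intercept_, weighted.intercept_, atol=1e-10)


def test_fit_requires_all_classes_seen():
    with pytest.raises(ValueError, match="two classes"):
        SoftmaxClassifier().fit(np.zeros((4, 1)), np.zeros(4))


def test_dimension_mismatch_raises():
    clf = _model(np.zeros((2, 3)), np.zeros(2), [0, 1])
    with pytest.raises(ValueError, match="dimension"):
        clf.predict_proba(np.zeros((5, 4)))


def test_hidden_layer_variant_trains_deterministically():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(40, 2))
    y = (X[:, 0] * X[:, 1] > 0).astype(int)  # XOR-like, non-linear
    a = SoftmaxClassifier(hidden_units=8, epochs=3000, seed=1).fit(X, y)
    b = SoftmaxClassifier(hidden_units=8, epochs=3000, seed=1).fit(X, y)
    assert np.array_equal(a.predict(X), b.predict(X))
    assert (a.predict(X) == y).mean() > 0.8


# -- evaluation --------------------------------------------------------------

def test_evaluate_perfect_predictor_diagonal():
    clf = _model([[10.0], [-10.0]], [0, 0], ["A", "B"])
    X = np.array([[1.0], [1.0], [-1.0]])
    y = np.array(["A", "A", "B"])
    acc, confusion, _ = evaluate(clf, X, y)
    assert acc == 100.0
    assert confusion.loc["A", "A"] == 2 and confusion.loc["B", "B"] == 1
    assert confusion.to_numpy().sum() == np.trace(confusion.to_numpy())


def test_evaluate_constant_predictor_single_column():
    clf = _model([[0.0], [0.0]], [1.0, 0.0], ["A", "B"])  # always predicts A
    X = np.zeros((6, 1))
    y = np.array(["A", "B", "B", "A", "B", "B"])
    acc, confusion, _ = evaluate(clf, X, y)
    assert acc == pytest.approx(100 * 2 / 6)
    assert (confusion["B"] == 0).all()
    assert confusion["A"].sum() == 6


def test_evaluate_matches_brute_force_tally():
    rng = np.random.default_rng(10)
    clf = _model(rng.normal(size=(3, 2)), rng.normal(size=3), ["P1", "P2", "P3"])
    X = rng.normal(size=(50, 2))
    y = rng.choice(["P1", "P2", "P3"], size=50)
    cont = {"P1": "Europe", "P2": "Europe", "P3": "Africa"}
    acc, confusion, per_cont = evaluate(clf, X, y, cont)
    pred = clf.predict(X)
    for t in clf.classes_:
        assert confusion.loc[t].sum() == (y == t).sum()  # rows sum to true counts
        for p in clf.classes_:
            assert confusion.loc[t, p] == int(((y == t) & (pred == p)).sum())
    assert acc == pytest.approx(100.0 * (pred == y).mean())
    for c in ("Europe", "Africa"):
        sel = np.array([cont[v] == c for v in y])
        expected = 100.0 * np.mean([cont[v] == c for v in pred[sel]])
        assert per_cont[c] == pytest.approx(expected)
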