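"""Softmax (multinomial logistic) ancestry classifier.

The model is the output layer of a softmax network: for class i,

    z_i = sum_j w_ij x_j + b_i,    t_i = exp(z_i),    a_i = t_i / sum_k t_k

and the predicted label is the argmax class.  With K = 2 this reduces to
binary logistic regression.  Training minimises the (optionally
L2-penalised) multinomial cross-entropy by full-batch gradient descent with
zero initialisation, so fits are deterministic.  An optional single hidden
layer (``hidden_units > 0``, tanh) is available for sensitivity analysis;
the default model is the plain softmax regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction; identical to exp/normalise."""
    z = z - z.max(axis=-1, keepdims=True)
    t = np.exp(z)
    return t / t.sum(axis=-1, keepdims=True)


class SoftmaxClassifier(BaseEstimator, ClassifierMixin):
    """K-class softmax regression trained by full-batch gradient descent.

    Parameters
    ----------
    learning_rate : float, default 0.1
    epochs : int, default 500
    l2 : float, default 1e-4
        L2 penalty on the weights (not the biases).
    hidden_units : int, default 0
        If positive, inserts one tanh hidden layer of this width (seeded
        random init); 0 gives plain softmax regression with zero init.
    seed : int, default 0
        Only consulted when ``hidden_units > 0``.

    Attributes
    ----------
    classes_ : ndarray of class labels in sorted order.
    coef_ : (K, F) weight matrix of the output layer.
    intercept_ : (K,) bias vector.
    loss_curve_ : per-epoch training loss.
    """

    def __init__(
        self,
        learning_rate: float = 0.1,
        epochs: int = 500,
        l2: float = 1e-4,
        hidden_units: int = 0,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.l2 = l2
        self.hidden_units = hidden_units
        self.seed = seed

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _loss_grad(
        W: np.ndarray,
        b: np.ndarray,
        X: np.ndarray,
        Y: np.ndarray,
        w_sample: np.ndarray,
        l2: float,
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Weighted-mean cross-entropy loss and its gradients in (W, b)."""
        P = softmax(X @ W.T + b)
        eps = 1e-300
        loss = -(w_sample @ (Y * np.log(P + eps)).sum(axis=1)) / w_sample.sum()
        loss += 0.5 * l2 * float((W * W).sum())
        R = (P - Y) * w_sample[:, None] / w_sample.sum()
        return float(loss), R.T @ X + l2 * W, R.sum(axis=0)

    def fit(self, X, y, sample_weight=None) -> "SoftmaxClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least two classes in the training labels")
        n, F = X.shape
        w_sample = (
            np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        )
        Y = np.zeros((n, K))
        Y[np.arange(n), y_idx] = 1.0

        if self.hidden_units > 0:
            self._fit_hidden(X, Y, w_sample)
            return self

        W = np.zeros((K, F))
        b = np.zeros(K)
        losses = np.empty(self.epochs)
        for epoch in range(self.epochs):
            loss, gW, gb = self._loss_grad(W, b, X, Y, w_sample, self.l2)
            losses[epoch] = loss
            W -= self.learning_rate * gW
            b -= self.learning_rate * gb
        self.coef_ = W
        self.intercept_ = b
        self.loss_curve_ = losses
        self._hidden = None
        return self

    def _fit_hidden(self, X, Y, w_sample) -> None:
        rng = np.random.default_rng(self.seed)
        n, F = X.shape
        K = Y.shape[1]
        H = self.hidden_units
        W1 = rng.normal(scale=0.1, size=(H, F))
        b1 = np.zeros(H)
        W2 = rng.normal(scale=0.1, size=(K, H))
        b2 = np.zeros(K)
        wn = w_sample / w_sample.sum()
        losses = np.empty(self.epochs)
        for epoch in range(self.epochs):
            A = np.tanh(X @ W1.T + b1)
            P = softmax(A @ W2.T + b2)
            losses[epoch] = -float(wn @ (Y * np.log(P + 1e-300)).sum(axis=1))
            R2 = (P - Y) * wn[:, None]
            R1 = (R2 @ W2) * (1 - A * A)
            W2 -= self.learning_rate * (R2.T @ A + self.l2 * W2)
            b2 -= self.learning_rate * R2.sum(axis=0)
            W1 -= self.learning_rate * (R1.T @ X + self.l2 * W1)
            b1 -= self.learning_rate * R1.sum(axis=0)
        self._hidden = (W1, b1)
        self.coef_ = W2
        self.intercept_ = b2
        self.loss_curve_ = losses

    def _logits(self, X: np.ndarray) -> np.ndarray:
        if getattr(self, "_hidden", None) is not None:
            W1, b1 = self._hidden
            X = np.tanh(X @ W1.T + b1)
        return X @ self.coef_.T + self.intercept_

    # -- prediction --------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.coef_.shape[1] and self._hidden is None:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.coef_.shape[1]}"
            )
        P = softmax(self._logits(X))
        return P[0] if single else P

    def predict(self, X) -> np.ndarray:
        """Argmax class; ties (within 1e-9 relative) resolve to the earliest
        class, so structurally symmetric classes are broken deterministically
        regardless of floating-point summation order."""
        P = self.predict_proba(X)
        P2 = np.atleast_2d(P)
        near_max = P2 >= P2.max(axis=1, keepdims=True) * (1 - 1e-9)
        idx = np.argmax(near_max, axis=1)  # first near-maximal class
        out = self.classes_[idx]
        return out[0] if np.ndim(P) == 1 else out


def evaluate(
    model: SoftmaxClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    pop_to_continent: dict[str, str] | None = None,
) -> tuple[float, pd.DataFrame, dict[str, float]]:
    """Test accuracy (%), confusion matrix and per-continent accuracy.

    A test individual from continent j counts as continent-correct iff the
    continent of the *predicted* class equals j (classes may themselves be
    continents, in which case the rule is plain accuracy per continent).
    """
    y_test = np.asarray(y_test)
    pred = model.predict(X_test)
    labels = list(model.classes_)
    cm = _sk_confusion(y_test, pred, labels=labels)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    accuracy = 100.0 * float((pred == y_test).mean())

    per_continent: dict[str, float] = {}
    if pop_to_continent is not None:
        to_cont = lambda v: pop_to_continent.get(v, v)  # noqa: E731
        true_cont = np.array([to_cont(v) for v in y_test])
        pred_cont = np.array([to_cont(v) for v in pred])
        for cont in sorted(set(true_cont)):
            sel = true_cont == cont
            per_continent[cont] = 100.0 * float((pred_cont[sel] == cont).mean())
    return accuracy, confusion, per_continent
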