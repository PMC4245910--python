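"""Classifiers and performance metrics for window-level decoding.

Two classifiers are supported, matching the decoding study design:

* shrinkage LDA — class means with a pooled covariance shrunk toward its
  diagonal (Ledoit-Wolf coefficient), robust when the feature dimension
  approaches the window count in small folds;
* RBF-kernel SVM with C = 0.6, decomposed one-against-one: k(k-1)/2 binary
  classifiers, majority vote, vote ties broken by the largest aggregate
  decision margin.  Features are z-scored (training statistics only)
  before the kernel, which is scale-sensitive; LDA sees raw log powers.

Metrics are computed from the confusion matrix: accuracy (trace / total)
and the Matthews correlation coefficient.  For two classes MCC is the
familiar (TP*TN - FP*FN) / sqrt(...) formula; for more classes the Rk
generalisation over the full confusion matrix is used, which reduces to
the binary formula at k = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters; C defaults to the study's 0.6."""

    C: float = 0.6
    gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


def _check_training_data(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    return features, labels


class LDAModel:
    """Shrinkage LDA; prediction ties resolve to the lowest class index.

    Class priors are uniform, not empirical: window counts per class follow
    block durations (SPN blocks are half as long as task blocks), and the
    decoder should not exploit that imbalance — with uniform priors the
    chance level stays 1/k for any test composition.
    """

    def __init__(self) -> None:
        self._est: LinearDiscriminantAnalysis | None = None

    def fit(self, features: np.ndarray, labels: Sequence) -> "LDAModel":
        features, labels = _check_training_data(features, np.asarray(labels))
        k = np.unique(labels).size
        self._est = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto", priors=np.full(k, 1.0 / k)
        )
        self._est.fit(features, labels)
        return self

    @property
    def classes_(self) -> np.ndarray:
        return self._est.classes_

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self._est.predict(np.asarray(features, dtype=float))


class OvoSVMModel:
    """One-against-one RBF-SVM with majority vote.

    libsvm's decomposition is already one-vs-one; the per-pair decision
    values are re-aggregated here so that vote ties break on the largest
    summed absolute margin rather than on class order.
    """

    def __init__(self, config: SVMConfig | None = None) -> None:
        self.config = config or SVMConfig()
        self._scaler = StandardScaler()
        self._est = SVC(
            C=self.config.C,
            kernel="rbf",
            gamma=self.config.gamma,
            decision_function_shape="ovo",
        )

    def fit(self, features: np.ndarray, labels: Sequence) -> "OvoSVMModel":
        features, labels = _check_training_data(features, np.asarray(labels))
        self._est.fit(self._scaler.fit_transform(features), labels)
        return self

    @property
    def classes_(self) -> np.ndarray:
        return self._est.classes_

    @property
    def n_binary_classifiers(self) -> int:
        k = len(self.classes_)
        return k * (k - 1) // 2

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = self._scaler.transform(np.asarray(features, dtype=float))
        classes = self.classes_
        k = len(classes)
        if k == 2:
            return self._est.predict(x)
        dec = self._est.decision_function(x)  # n x k(k-1)/2, pair order (i,j) i<j
        votes = np.zeros((x.shape[0], k))
        margin = np.zeros((x.shape[0], k))
        for col, (i, j) in enumerate(combinations(range(k), 2)):
            d = dec[:, col]
            winner_i = d > 0  # positive decision favours the first class of the pair
            votes[winner_i, i] += 1
            votes[~winner_i, j] += 1
            margin[:, i] += np.abs(d) * winner_i
            margin[:, j] += np.abs(d) * ~winner_i
        # argmax on votes, vote ties broken by aggregate margin (scaled below
        # 1 vote), residual exact ties by lowest class index (np.argmax)
        margin_scaled = margin / (1.0 + margin.max()) if margin.max() > 0 else margin
        return classes[np.argmax(votes + margin_scaled, axis=1)]


def train_lda(features: np.ndarray, labels: Sequence) -> LDAModel:
    """Fit shrinkage LDA on labelled window features."""
    return LDAModel().fit(features, labels)


def train_svm_rbf(
    features: np.ndarray, labels: Sequence, config: SVMConfig | None = None
) -> OvoSVMModel:
    """Fit the one-against-one RBF-SVM (z-scored features, C = 0.6)."""
    return OvoSVMModel(config).fit(features, labels)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, classes: Sequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """k x k counts (rows = true, columns = predicted) and the class order."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    else:
        classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return mat, classes


def accuracy(confusion: np.ndarray) -> float:
    """Fraction of correctly classified windows: trace / total."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def mcc(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient of a confusion matrix, in [-1, 1].

    Implements the multi-category Rk statistic

        (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))

    with c = trace, s = total, t_k / p_k the row / column sums; for a 2x2
    matrix this equals (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Returns 0 when a denominator factor vanishes (all-one-class edge case).
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    s = confusion.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    c = np.trace(confusion)
    t = confusion.sum(axis=1)  # true-class totals
    p = confusion.sum(axis=0)  # predicted-class totals
    num = c * s - t @ p
    den_sq = (s**2 - p @ p) * (s**2 - t @ t)
    if den_sq <= 0:
        return 0.0
    return float(num / np.sqrt(den_sq))
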