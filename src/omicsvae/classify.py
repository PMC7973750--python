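"""Cross-validated classification of cancer status / molecular subtype from LFs.

The ANN classifier mirrors the supervised head of the model: input width =
LF count, one hidden layer of half that width, softmax output; trained with
Adam (1e-3) and early stopping on training loss.  The SVM comparison
classifier is a grid-tuned RBF support-vector machine.  Both are evaluated
with seeded stratified 5-fold cross-validation and report accuracy (%),
macro precision / recall / f1 as mean +/- sd over folds, plus the confusion
matrix summed over held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .autodiff import Tensor
from .nn import Adam, DenseBlock, Linear, Module
from .losses import softmax_cross_entropy

__all__ = ["CVReport", "ann_classify_cv", "svm_classify_cv", "confusion_matrix"]


@dataclass
class CVReport:
    """Per-fold metrics with mean +/- sd aggregates; accuracy on the % scale."""

    fold_accuracy: List[float]  # percent
    fold_precision: List[float]
    fold_recall: List[float]
    fold_f1: List[float]
    confusion: np.ndarray  # summed over held-out folds
    class_order: List

    def _agg(self, vals):
        return float(np.mean(vals)), float(np.std(vals))

    @property
    def accuracy(self):  # (mean, sd) in percent
        return self._agg(self.fold_accuracy)

    @property
    def precision(self):
        return self._agg(self.fold_precision)

    @property
    def recall(self):
        return self._agg(self.fold_recall)

    @property
    def f1(self):
        return self._agg(self.fold_f1)

    def summary(self) -> Dict[str, str]:
        fmt = lambda m, s: f"{m:.3g} ± {s:.2g}"
        return {
            "accuracy": fmt(*self.accuracy),
            "precision": fmt(*self.precision),
            "recall": fmt(*self.recall),
            "f1": fmt(*self.f1),
        }


def confusion_matrix(true_labels, predicted_labels, class_order) -> np.ndarray:
    """Entry (i, j): count of true class_order[i] predicted as class_order[j]."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    unknown = set(true_labels) | set(predicted_labels)
    unknown -= set(class_order)
    if unknown:
        raise ValueError(f"label(s) outside class_order: {sorted(unknown)}")
    out = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        out[index[t], index[p]] += 1
    return out


class _ANN(Module):
    """Input -> half-width hidden (BN + ReLU) -> softmax output."""

    def __init__(self, n_in: int, n_classes: int, rng):
        self.hidden = DenseBlock(n_in, max(n_in // 2, 2), rng)
        self.out = Linear(max(n_in // 2, 2), n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.out(self.hidden(x))


def _train_ann(X: np.ndarray, y: np.ndarray, n_classes: int, seed: int,
               epochs: int = 500, batch_size: int = 32,
               patience: int = 50) -> _ANN:
    rng = np.random.default_rng(seed)
    net = _ANN(X.shape[1], n_classes, rng)
    opt = Adam(net.parameters(), lr=1e-3)
    best, wait = np.inf, patience
    n = len(X)
    net.train()
    for _ in range(epochs):
        perm = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            if len(idx) < 2:
                continue
            logits = net(Tensor(X[idx]))
            loss = softmax_cross_entropy(logits, y[idx])
            net.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        epoch_loss /= max(n_batches, 1)
        if epoch_loss < best:
            best, wait = epoch_loss, patience
        else:
            wait -= 1
            if wait <= 0:
                break
    net.eval()
    return net


def _predict_ann(net: _ANN, X: np.ndarray) -> np.ndarray:
    return np.argmax(net(Tensor(X)).data, axis=1)


def _cv_report(lfs, labels, folds, seed, fit_predict) -> CVReport:
    X = np.asarray(lfs, float)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds; "
            "use fewer folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc, prec, rec, f1 = [], [], [], []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y_idx)):
        pred = fit_predict(X[tr], y_idx[tr], X[te], seed + fold)
        acc.append(100.0 * np.mean(pred == y_idx[te]))
        p, r, f, _ = precision_recall_fscore_support(
            y_idx[te], pred, average="macro", zero_division=0)
        prec.append(p)
        rec.append(r)
        f1.append(f)
        confusion += confusion_matrix(y_idx[te], pred, list(range(len(classes))))
    return CVReport(acc, prec, rec, f1, confusion, list(classes))


def ann_classify_cv(lfs, labels, folds: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold CV of the 3-layer ANN classifier on the LF matrix."""
    n_classes = len(np.unique(labels))

    def fit_predict(Xtr, ytr, Xte, fold_seed):
        net = _train_ann(Xtr, ytr, n_classes, fold_seed)
        return _predict_ann(net, Xte)

    return _cv_report(lfs, labels, folds, seed, fit_predict)


def svm_classify_cv(lfs, labels, folds: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold CV of a grid-tuned RBF support-vector classifier."""

    def fit_predict(Xtr, ytr, Xte, fold_seed):
        inner = min(5, int(np.bincount(ytr).min()))
        if inner >= 2:
            clf = GridSearchCV(SVC(kernel="rbf"),
                               {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
                               cv=inner, n_jobs=1)
        else:
            clf = SVC(kernel="rbf")
        clf.fit(Xtr, ytr)
        return clf.predict(Xte)

    return _cv_report(lfs, labels, folds, seed, fit_predict)
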