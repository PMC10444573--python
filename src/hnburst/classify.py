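"""LA/HA bursting-regime labeling and a Gaussian naive Bayes classifier.

Bursting epochs are labeled high-amplitude (1) when both the voltage-envelope
amplitude and the [Na+]_i oscillation amplitude exceed expert thresholds
(20 mV, 1 mM), low-amplitude (0) otherwise.  A from-scratch Gaussian naive
Bayes model, exposed as a scikit-learn-style estimator, is trained on a
seeded 35% split and evaluated on the remaining 65% with a standard
classification report.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "two_threshold_label",
    "GaussianNaiveBayes",
    "classification_report",
    "train_test_split_35",
]


def two_threshold_label(v_amp, na_amp, v_thr: float = 0.020,
                        na_thr: float = 0.001):
    """1 iff both amplitudes strictly exceed their thresholds, else 0."""
    v_amp = np.asarray(v_amp, dtype=float)
    na_amp = np.asarray(na_amp, dtype=float)
    out = ((v_amp > v_thr) & (na_amp > na_thr)).astype(int)
    return out if out.ndim else int(out)


class GaussianNaiveBayes:
    """Gaussian naive Bayes with maximum-likelihood parameters.

    Scikit-learn estimator conventions: ``fit``/``predict``/``predict_proba``
    and fitted attributes with trailing underscores.  Per-class feature
    variances are floored at ``var_floor_frac`` of the largest feature
    variance to keep posteriors finite on degenerate features.
    """

    def __init__(self, var_floor_frac: float = 1e-9):
        self.var_floor_frac = var_floor_frac

    def get_params(self, deep: bool = True) -> dict:
        return {"var_floor_frac": self.var_floor_frac}

    def set_params(self, **params) -> "GaussianNaiveBayes":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "GaussianNaiveBayes":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set must contain both classes")
        self.classes_ = classes
        n, d = X.shape
        self.theta_ = np.empty((classes.size, d))
        self.var_ = np.empty((classes.size, d))
        self.class_prior_ = np.empty(classes.size)
        for i, c in enumerate(classes):
            Xc = X[y == c]
            self.theta_[i] = Xc.mean(axis=0)
            self.var_[i] = Xc.var(axis=0)
            self.class_prior_[i] = Xc.shape[0] / n
        floor = self.var_floor_frac * max(self.var_.max(), 1.0)
        self.var_ = np.maximum(self.var_, floor)
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        jll = np.empty((X.shape[0], self.classes_.size))
        for i in range(self.classes_.size):
            ll = -0.5 * np.sum(
                np.log(2.0 * np.pi * self.var_[i])
                + (X - self.theta_[i]) ** 2 / self.var_[i], axis=1)
            jll[:, i] = np.log(self.class_prior_[i]) + ll
        return jll

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)


def train_test_split_35(X, y, train_frac: float = 0.35, seed: int = 0,
                        stratify: bool = True):
    """Seeded 35/65 split, stratified by class when possible.

    Returns ``(X_train, X_test, y_train, y_test)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    if stratify:
        train_idx = []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            k = max(1, int(round(train_frac * idx.size)))
            train_idx.extend(idx[:k])
        train_idx = np.sort(np.asarray(train_idx))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[: max(1, int(round(train_frac * n)))])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return X[mask], X[~mask], y[mask], y[~mask]


def classification_report(y_true, y_pred) -> dict:
    """Per-class precision/recall/F1/support plus accuracy and averages.

    Precision is TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean;
    weighted averages weight by class support.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label lists")
    if y_true.shape != y_pred.shape:
        raise ValueError("label lists must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    report: dict = {}
    precs, recs, f1s, sups = [], [], [], []
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        sup = int(np.sum(y_true == c))
        report[str(c)] = {"precision": prec, "recall": rec,
                          "f1-score": f1, "support": sup}
        precs.append(prec); recs.append(rec); f1s.append(f1); sups.append(sup)
    sups_arr = np.asarray(sups, dtype=float)
    w = sups_arr / sups_arr.sum()
    report["accuracy"] = float(np.mean(y_true == y_pred))
    report["macro avg"] = {
        "precision": float(np.mean(precs)), "recall": float(np.mean(recs)),
        "f1-score": float(np.mean(f1s)), "support": int(sups_arr.sum()),
    }
    report["weighted avg"] = {
        "precision": float(np.dot(w, precs)), "recall": float(np.dot(w, recs)),
        "f1-score": float(np.dot(w, f1s)), "support": int(sups_arr.sum()),
    }
    return report
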