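"""Discriminant modeling of single-, cross- and multi-block matrices.

The classifier is classical multi-class LDA solved as the generalized
eigenproblem of the between-class scatter against the (ridge-regularized)
within-class scatter.  With six classes there are at most five discriminant
axes; score plots use the first two.  Classification assigns the nearest
class centroid in the full discriminant space.  Performance is summarized
by stratified k-fold cross-validated accuracy (mean +/- SD over folds),
optionally re-fitting the auto-scaler inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .blocks import BlockScaler, FeatureBlock


class LinearDiscriminantModel(BaseEstimator, ClassifierMixin):
    """Multi-class LDA via the within/between scatter eigenproblem.

    Parameters
    ----------
    n_components : int or None
        Number of discriminant axes to keep; None keeps ``n_classes - 1``.
    ridge : float
        Within-scatter shrinkage ``S_w + ridge * (tr(S_w)/p) * I``, making
        the solver well defined when features outnumber the within-class
        degrees of freedom.

    Fitted attributes
    -----------------
    classes_, means_, xbar_ : class labels, class means, grand mean
    scalings_ : (n_features, n_kept) discriminant axes, unit norm,
        sign-fixed (largest-magnitude loading positive)
    eigenvalues_ : generalized eigenvalues, descending
    explained_variance_ratio_ : eigenvalue fractions of the kept axes
    centroids_ : class means projected into discriminant space
    """

    def __init__(self, n_components: int | None = None, ridge: float = 1e-6):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = self.classes_.size
        n, p = X.shape
        if k < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 samples")
        max_axes = k - 1
        n_keep = max_axes if self.n_components is None else self.n_components
        if n_keep > max_axes:
            raise ValueError(f"n_components={n_keep} exceeds n_classes-1={max_axes}")

        self.xbar_ = X.mean(axis=0)
        self.means_ = np.vstack([X[y_idx == c].mean(axis=0) for c in range(k)])
        Sw = np.zeros((p, p))
        for c in range(k):
            d = X[y_idx == c] - self.means_[c]
            Sw += d.T @ d
        dm = self.means_ - self.xbar_
        Sb = (dm * counts[:, None]).T @ dm
        Sw_reg = Sw + self.ridge * (np.trace(Sw) / p) * np.eye(p)

        eigvals, eigvecs = linalg.eigh(Sb, Sw_reg)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)[:max_axes]
        axes = eigvecs[:, order][:, :max_axes]
        axes /= np.linalg.norm(axes, axis=0, keepdims=True)
        flip = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(axes.shape[1])])
        axes *= np.where(flip == 0, 1.0, flip)

        total = eigvals.sum()
        self.eigenvalues_ = eigvals[:n_keep]
        self.scalings_ = axes[:, :n_keep]
        self.explained_variance_ratio_ = (
            self.eigenvalues_ / total if total > 0 else np.zeros(n_keep)
        )
        self.centroids_ = (self.means_ - self.xbar_) @ self.scalings_
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "scalings_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fit with {self.n_features_in_}"
            )
        return (X - self.xbar_) @ self.scalings_

    def predict(self, X) -> np.ndarray:
        scores = self.transform(X)
        d2 = ((scores[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


@dataclass
class LDAResult:
    """Fitted discriminant summary with 2-D scores for plotting."""

    model: LinearDiscriminantModel
    scores: pd.DataFrame            # sample x (LD1, LD2, class)
    explained_variance: np.ndarray  # fractions per kept axis
    eigenvalues: np.ndarray


def lda_fit(X, y=None, n_components: int | None = None, ridge: float = 1e-6) -> LDAResult:
    """Fit LDA and bundle LD1/LD2 scores with the class labels.

    ``X`` may be a DataFrame or array of (already auto-scaled) features;
    ``n_components`` limits the *reported* axes, classification always uses
    the full discriminant space.
    """
    if isinstance(X, FeatureBlock):
        X, y = X.data, X.labels
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    model = LinearDiscriminantModel(n_components=None, ridge=ridge).fit(
        np.asarray(X, dtype=float), y
    )
    scores = model.transform(np.asarray(X, dtype=float))
    n_show = min(2, scores.shape[1]) if n_components is None else n_components
    df = pd.DataFrame(
        scores[:, :n_show], index=index,
        columns=[f"LD{i+1}" for i in range(n_show)],
    )
    df["class"] = np.asarray(y)
    return LDAResult(model=model, scores=df,
                     explained_variance=model.explained_variance_ratio_[:n_show],
                     eigenvalues=model.eigenvalues_)


def lda_transform(result: LDAResult, X_new) -> np.ndarray:
    """Project new samples with the stored centering and axes."""
    return result.model.transform(np.asarray(X_new, dtype=float))


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    mean: float
    sd: float

    @classmethod
    def from_folds(cls, accs) -> "CVResult":
        accs = np.asarray(accs, dtype=float)
        return cls(fold_accuracies=accs, mean=float(accs.mean()), sd=float(accs.std(ddof=0)))


def cv_accuracy(X, y=None, folds: int = 5, seed: int = 0,
                scale_mode: str = "global", ridge: float = 1e-6) -> CVResult:
    """Stratified k-fold cross-validated LDA accuracy.

    ``scale_mode="global"`` assumes ``X`` was auto-scaled once on the full
    data set before CV (the protocol of scaling prior to analysis; a mild
    leakage documented in the methods note); ``"per_fold"`` re-fits the
    scaler on each training fold only.
    """
    if isinstance(X, FeatureBlock):
        X, y = X.data, X.labels
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    _, counts = np.unique(ya, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"smallest class ({counts.min()}) is below folds={folds}")
    if scale_mode not in ("global", "per_fold"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(Xa, ya):
        Xtr, Xte = Xa[train], Xa[test]
        if scale_mode == "per_fold":
            scaler = BlockScaler().fit(Xtr)
            Xtr = scaler.transform(Xtr).to_numpy()
            Xte = scaler.transform(Xte).to_numpy()
        model = LinearDiscriminantModel(ridge=ridge).fit(Xtr, ya[train])
        accs.append(float(np.mean(model.predict(Xte) == ya[test])))
    return CVResult.from_folds(accs)
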