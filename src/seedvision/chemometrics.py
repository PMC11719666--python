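"""PCA, PLS-DA, permutation testing, VIP scores and marker selection.

The discrimination layer mirrors standard chemometric practice:

* PCA on the autoscaled (mean-centered, unit-variance) feature table,
  with explained-variance percentages from the singular values;
* PLS-DA: partial least squares (NIPALS PLS2 with deflation) against a
  centered one-hot class matrix; class prediction is the argmax of the
  predicted dummy scores. Model quality is summarized by R2Y (fitted
  fraction of label variance) and Q2 (PRESS/SS from stratified 7-fold
  cross-validation, the default of the chemometrics software this
  workflow follows);
* a label-permutation test (200 rounds by default) guarding against
  overfitting, with the empirical p-value
  (#{permuted Q2 >= original Q2} + 1) / (nperm + 1);
* VIP scores, VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a) with
  unit-norm weight vectors, so that sum_j VIP_j^2 = p;
* per-feature one-way ANOVA F-tests, and the marker rule that keeps
  features with VIP > 1 and p < 0.05 (both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PCAResult", "PLSDAModel", "MarkerSelection", "PermutationResult",
    "pca", "plsda_fit", "vip", "permutation_test",
    "one_way_anova", "anova_pvalues", "select_markers",
]


# --------------------------------------------------------------------------
# helpers

def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D table")
    return X, [f"x{j}" for j in range(X.shape[1])]


def _autoscale(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        bad = ", ".join(names[j] for j in zero)
        raise ValueError(f"zero-variance column(s) under autoscaling: {bad}")
    return (X - mean) / sd, mean, sd


def _one_hot(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(np.float64)
    return Y, classes


# --------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: np.ndarray        # n x A
    loadings: np.ndarray      # p x A, orthonormal columns
    explained_pct: np.ndarray # A percentages, non-increasing
    feature_names: list[str] = field(default_factory=list)


def pca(X, ncomp: int | None = None, autoscale: bool = True) -> PCAResult:
    """Principal components of a feature table via the SVD.

    ``explained_pct`` holds the first ``ncomp`` percentages; over all
    min(n-1, p) components they sum to 100. Autoscaling (default)
    requires every column to have positive variance and raises an error
    naming any constant column.
    """
    X, names = _as_matrix(X)
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("PCA needs n >= 2 samples and p >= 1 features")
    full = min(n - 1, p)
    if ncomp is None:
        ncomp = full
    if not 1 <= ncomp <= full:
        raise ValueError(f"ncomp must lie in [1, {full}], got {ncomp}")
    if autoscale:
        Xs, _, _ = _autoscale(X, names)
    else:
        Xs = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    var = s ** 2
    pct = 100.0 * var / var.sum()
    scores = Xs @ Vt.T[:, :ncomp]
    return PCAResult(scores=scores, loadings=Vt.T[:, :ncomp],
                     explained_pct=pct[:ncomp], feature_names=names)


# --------------------------------------------------------------------------
# PLS-DA

@dataclass
class PLSDAModel:
    n_components: int
    x_scores: np.ndarray        # n x A (t vectors)
    x_weights: np.ndarray       # p x A, unit-norm columns
    y_loadings: np.ndarray      # k x A
    ssy: np.ndarray             # explained Y sum of squares per component
    r2y: float
    q2: float
    vip: np.ndarray             # p-vector
    classes: np.ndarray
    feature_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    _pls: PLSRegression = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        """Class labels via argmax of the predicted dummy scores."""
        X, _ = _as_matrix(X)
        Xs = (X - self.x_mean) / self.x_std
        Yhat = self._pls.predict(Xs) + self.y_mean
        return self.classes[np.argmax(Yhat, axis=1)]


def _fit_limits(n: int, p: int) -> int:
    return max(1, min(n - 1, p))


def _vip_scores(W: np.ndarray, ssy: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    num = (Wn ** 2) @ ssy
    return np.sqrt(p * num / ssy.sum())


def _q2_cv(X: np.ndarray, Y: np.ndarray, labels: np.ndarray, ncomp: int,
           n_folds: int = 7) -> float:
    """Q2 = 1 - PRESS/SS under stratified k-fold cross-validation."""
    _, counts = np.unique(labels, return_counts=True)
    n_folds = min(n_folds, int(counts.min()))
    if n_folds < 2:
        raise ValueError("Q2 cross-validation needs every class >= 2 members")
    skf = StratifiedKFold(n_splits=n_folds)   # deterministic, no shuffling
    press = 0.0
    ss = 0.0
    for tr, te in skf.split(X, labels):
        mx = X[tr].mean(axis=0)
        sx = X[tr].std(axis=0, ddof=0)
        sx = np.where(sx > 0, sx, 1.0)
        my = Y[tr].mean(axis=0)
        a = min(ncomp, _fit_limits(len(tr), X.shape[1]))
        pls = PLSRegression(n_components=a, scale=False)
        pls.fit((X[tr] - mx) / sx, Y[tr] - my)
        Yhat = pls.predict((X[te] - mx) / sx) + my
        press += float(((Y[te] - Yhat) ** 2).sum())
        ss += float(((Y[te] - my) ** 2).sum())
    return 1.0 - press / ss


def plsda_fit(X, labels, ncomp: int = 3, n_folds: int = 7) -> PLSDAModel:
    """Fit a PLS-DA model on a raw feature table.

    X is autoscaled internally; Y is the centered one-hot class matrix.
    ``ncomp`` is truncated (with a warning) if it exceeds what the data
    can support.
    """
    X, names = _as_matrix(X)
    Y, classes = _one_hot(labels)
    labels = np.asarray(labels)
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    if np.unique(labels, return_counts=True)[1].min() < 2:
        raise ValueError("every class needs at least 2 members")
    n, p = X.shape
    limit = _fit_limits(n, p)
    if ncomp > limit:
        warnings.warn(f"ncomp={ncomp} exceeds the data rank limit; using {limit}")
        ncomp = limit

    Xs, x_mean, x_std = _autoscale(X, names)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(Xs, Yc)
    T = pls.x_scores_                      # n x A, mutually orthogonal
    W = pls.x_weights_                     # p x A, unit norm
    Q = pls.y_loadings_                    # k x A

    ssy = (T ** 2).sum(axis=0) * (Q ** 2).sum(axis=0)
    Yhat = T @ Q.T
    r2y = 1.0 - float(((Yc - Yhat) ** 2).sum()) / float((Yc ** 2).sum())
    q2 = _q2_cv(X, Y, labels, ncomp, n_folds=n_folds)
    vip_vec = _vip_scores(W, ssy)

    return PLSDAModel(n_components=ncomp, x_scores=T, x_weights=W,
                      y_loadings=Q, ssy=ssy, r2y=r2y, q2=q2, vip=vip_vec,
                      classes=classes, feature_names=names,
                      x_mean=x_mean, x_std=x_std, y_mean=y_mean, _pls=pls)


def vip(model: PLSDAModel) -> np.ndarray:
    """Variable-importance-in-projection scores of a fitted model."""
    return _vip_scores(model.x_weights, model.ssy)


# --------------------------------------------------------------------------
# permutation test

@dataclass
class PermutationResult:
    table: pd.DataFrame      # rows: original first, then one per permutation
    p_value: float
    model: PLSDAModel


def permutation_test(X, labels, ncomp: int = 3, nperm: int = 200,
                     seed: int = 0, n_folds: int = 7) -> PermutationResult:
    """Label-permutation validation of a PLS-DA model.

    Refits the model ``nperm`` times on shuffled labels, recording the
    correlation of the permuted one-hot labels with the originals and
    the permuted R2Y/Q2. The table has nperm + 1 rows (original first).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    labels = np.asarray(labels)
    model = plsda_fit(X, labels, ncomp=ncomp, n_folds=n_folds)
    Yo, _ = _one_hot(labels)
    Yo_c = (Yo - Yo.mean(axis=0)).ravel()
    rows = [{"permuted": False, "label_correlation": 1.0,
             "R2Y": model.r2y, "Q2": model.q2}]
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(nperm):
        perm = rng.permutation(labels.size)
        lp = labels[perm]
        m = plsda_fit(X, lp, ncomp=ncomp, n_folds=n_folds)
        Yp = Yo[perm]
        Yp_c = (Yp - Yp.mean(axis=0)).ravel()
        denom = np.linalg.norm(Yo_c) * np.linalg.norm(Yp_c)
        corr = float(Yo_c @ Yp_c / denom) if denom > 0 else 0.0
        if m.q2 >= model.q2:
            n_ge += 1
        rows.append({"permuted": True, "label_correlation": corr,
                     "R2Y": m.r2y, "Q2": m.q2})
    p_value = (n_ge + 1) / (nperm + 1)
    return PermutationResult(table=pd.DataFrame(rows), p_value=p_value,
                             model=model)


# --------------------------------------------------------------------------
# ANOVA and marker selection

def one_way_anova(X, labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-column one-way ANOVA; returns (F, p) vectors.

    Columns that are constant within and between groups get F = 0,
    p = 1 (no evidence of a group effect).
    """
    X, _ = _as_matrix(X)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("ANOVA needs >= 2 groups with >= 2 members each")
    groups = [X[labels == c] for c in classes]
    F = np.empty(X.shape[1])
    P = np.empty(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(X.shape[1]):
            f, p = stats.f_oneway(*(g[:, j] for g in groups))
            if not np.isfinite(f):
                if np.isinf(f):      # zero within-group, nonzero between
                    F[j], P[j] = np.inf, 0.0
                else:                # fully degenerate column
                    F[j], P[j] = 0.0, 1.0
            else:
                F[j], P[j] = float(f), float(p)
    return F, P


def anova_pvalues(X, labels) -> np.ndarray:
    """One-way ANOVA p-value per feature column."""
    return one_way_anova(X, labels)[1]


@dataclass
class MarkerSelection:
    names: list[str]
    vip: np.ndarray
    pvalues: np.ndarray

    def __contains__(self, name: str) -> bool:
        return name in self.names


def select_markers(vip_scores, pvalues, names) -> MarkerSelection:
    """Features with VIP > 1 and p < 0.05, both strict."""
    vip_scores = np.asarray(vip_scores, dtype=np.float64)
    pvalues = np.asarray(pvalues, dtype=np.float64)
    names = list(names)
    if not (len(vip_scores) == len(pvalues) == len(names)):
        raise ValueError("vip, pvalues and names must have equal length")
    keep = (vip_scores > 1.0) & (pvalues < 0.05)
    idx = np.nonzero(keep)[0]
    return MarkerSelection(names=[names[i] for i in idx],
                           vip=vip_scores[idx], pvalues=pvalues[idx])
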