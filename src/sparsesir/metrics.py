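"""Downstream prediction and the evaluation metrics.

Sufficient predictors are the projected scores U = X V; categorical
prediction is nearest centroid in score space.  Selection quality is
summarized by TPR/FPR on the row support, estimation quality by the mean
absolute correlation between true and estimated sufficient predictors
and by the projection (subspace) distance

    Delta(Vhat, V) = || P_Vhat - P_V ||_F,

with P the orthogonal projector onto the column span.  All metrics are
proportions or nonnegative distances; scaling x100 for display is left
to the reporting layer.
"""

from __future__ import annotations

import numpy as np


def _basis_matrix(basis) -> np.ndarray:
    return np.asarray(getattr(basis, "v_hat", basis), dtype=float)


def canonical_normalize(basis, sigma_hat: np.ndarray) -> np.ndarray:
    """Rescale a basis to canonical discriminant coordinates.

    Returns V T with T = (V' Sigma V)^{-1/2} (eigenvalues clipped at
    1e-12), so that the scores U = X V T have approximately identity
    within covariance — the normalization under which nearest-centroid
    classification on the scores behaves like discriminant analysis.
    T mixes columns only, so zero rows and the support are untouched.
    """
    V = _basis_matrix(basis)
    G = V.T @ np.asarray(sigma_hat, dtype=float) @ V
    w, U = np.linalg.eigh(0.5 * (G + G.T))
    w = np.maximum(w, 1e-12)
    return V @ (U / np.sqrt(w)) @ U.T


def sufficient_predictors(X: np.ndarray, basis) -> np.ndarray:
    """Scores U = X V (rows = samples, columns = directions)."""
    X = np.asarray(X, dtype=float)
    V = _basis_matrix(basis)
    if X.shape[1] != V.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns but the basis has {V.shape[0]} rows")
    return X @ V


def nearest_centroid(train_scores: np.ndarray, train_labels,
                     test_scores: np.ndarray) -> np.ndarray:
    """Assign each test point the class with the nearest training centroid.

    Distance ties are broken toward the smallest class label in sorted
    order.
    """
    train_scores = np.atleast_2d(np.asarray(train_scores, dtype=float))
    test_scores = np.atleast_2d(np.asarray(test_scores, dtype=float))
    train_labels = np.asarray(train_labels)
    if len(train_labels) == 0:
        raise ValueError("empty training set")
    labels = np.unique(train_labels)  # sorted, so argmin tie-break is correct
    centroids = np.vstack([
        train_scores[train_labels == lab].mean(axis=0) for lab in labels])
    d2 = ((test_scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return labels[np.argmin(d2, axis=1)]


def selection_metrics(est_support, true_support, p: int) -> tuple[float, float]:
    """(TPR, FPR) of the estimated support against the truth.

    TPR = |est ∩ true| / |true|; FPR = |est \\ true| / (p - |true|).
    """
    est = set(int(i) for i in np.asarray(est_support).ravel())
    true = set(int(i) for i in np.asarray(true_support).ravel())
    if not true:
        raise ValueError("true support must be nonempty")
    tpr = len(est & true) / len(true)
    fpr = len(est - true) / (p - len(true)) if p > len(true) else 0.0
    return tpr, fpr


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant score vector: correlation undefined")
    return abs(float(np.corrcoef(a, b)[0, 1]))


def predictor_correlation(true_basis, est_basis, X: np.ndarray) -> float:
    """Mean |Pearson correlation| between true and estimated predictors.

    Columns of the estimate are aligned to the truth by greedy maximum
    absolute correlation without replacement, then the matched |corr|
    values are averaged.  Sign and scale of either basis are irrelevant.
    """
    U_true = sufficient_predictors(X, true_basis)
    U_est = sufficient_predictors(X, est_basis)
    d = U_true.shape[1]
    if U_est.shape[1] != d:
        raise ValueError("bases must have the same number of columns")
    C = np.empty((d, d))
    for j in range(d):
        for k in range(d):
            C[j, k] = _abs_corr(U_true[:, j], U_est[:, k])
    total, rows, cols = 0.0, set(range(d)), set(range(d))
    for _ in range(d):
        j, k = max(((j, k) for j in rows for k in cols),
                   key=lambda jk: C[jk[0], jk[1]])
        total += C[j, k]
        rows.discard(j)
        cols.discard(k)
    return total / d


def projection_distance(v_hat, v_true) -> float:
    """Frobenius distance between the two spans' orthogonal projectors."""
    A = _basis_matrix(v_hat)
    B = _basis_matrix(v_true)
    projs = []
    for M in (A, B):
        if M.ndim != 2 or np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("basis must have full column rank")
        Q, _ = np.linalg.qr(M)
        projs.append(Q @ Q.T)
    return float(np.linalg.norm(projs[0] - projs[1], ord="fro"))


def misclassification_rate(pred, truth) -> float:
    """Fraction of mismatched labels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(pred != truth))
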