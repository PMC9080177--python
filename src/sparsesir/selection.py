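"""Data-driven choice of the sparsity level tau.

The constraint level tau has a natural upper bound: once
tau >= max_i ||b_i||_1 every row is screened out and the solution is
identically zero.  Candidates are therefore taken log-spaced inside
(0, tau_max).  A categorical response is tuned by K-fold cross-validated
nearest-centroid misclassification; a continuous response by the
BIC-type criterion

    BIC(tau) = n log G(tau) + log(n) s(tau),

where G(tau) = tr{V^T Sigma V - V^T M V} / tr{V^T M V} is the average
squared residual of the fitted basis V = V(tau) and s(tau) its number of
nonzero rows.  Candidates with a zero basis, a nonpositive kernel trace,
or nonpositive G are excluded from contention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dantzig import row_targets, solve_program
from .metrics import (
    canonical_normalize,
    misclassification_rate,
    nearest_centroid,
    sufficient_predictors,
)
from .sir import Dataset, SeedEstimates, WhitenedKernel, compute_moments, slice_response, whitened_kernel

logger = logging.getLogger(__name__)


@dataclass
class TuningResult:
    """Trace of a tuning run over the tau grid."""

    grid: np.ndarray
    scores: np.ndarray
    s_values: np.ndarray
    tau_opt: float
    g_values: np.ndarray | None = None
    criterion: str = "bic"


def tau_grid(kernel: WhitenedKernel, n_points: int = 25) -> np.ndarray:
    """Log-spaced candidate levels strictly inside (0, tau_max).

    tau_max = max_i ||b_i||_1 with B = K Vtilde, the level at which the
    program's solution becomes identically zero.
    """
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    B = row_targets(kernel)
    tau_max = float(np.abs(B).sum(axis=1).max())
    if tau_max <= 0:
        raise ValueError("kernel is zero: tau_max = 0, nothing to tune")
    return np.geomspace(1e-3 * tau_max, (1.0 - 1e-9) * tau_max, n_points,
                        endpoint=False)


def _argmin_prefer_sparse(grid: np.ndarray, scores: np.ndarray) -> float:
    """Smallest score; ties go to the largest tau (sparsest model)."""
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("every candidate was dropped from contention")
    best = np.nanmin(np.where(finite, scores, np.inf))
    ties = grid[finite & (scores <= best + 1e-12)]
    return float(ties.max())


def bic_select(kernel: WhitenedKernel, seed_est: SeedEstimates,
               grid, n: int) -> TuningResult:
    """BIC-type selection for a continuous response."""
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty tau grid")
    sigma, m = seed_est.sigma_hat, seed_est.m_hat
    scores = np.full(grid.shape, np.nan)
    g_vals = np.full(grid.shape, np.nan)
    s_vals = np.zeros(grid.shape, dtype=int)
    for i, tau in enumerate(grid):
        basis = solve_program(kernel, tau)
        s_vals[i] = basis.s_tau
        if basis.s_tau == 0:
            continue
        V = basis.v_hat
        t_m = float(np.trace(V.T @ m @ V))
        if t_m <= 0:
            logger.debug("tau=%.4g dropped: tr(V'MV)=%.3g <= 0", tau, t_m)
            continue
        g = (float(np.trace(V.T @ sigma @ V)) - t_m) / t_m
        g_vals[i] = g
        if g <= 0:
            logger.debug("tau=%.4g dropped: G=%.3g <= 0", tau, g)
            continue
        scores[i] = n * np.log(g) + np.log(n) * basis.s_tau
    tau_opt = _argmin_prefer_sparse(grid, scores)
    return TuningResult(grid=grid, scores=scores, s_values=s_vals,
                        g_values=g_vals, tau_opt=tau_opt, criterion="bic")


def cv_select(data: Dataset, grid, K: int = 5, seed: int = 0,
              d: int | None = None, precision_factory=None) -> TuningResult:
    """Stratified K-fold CV misclassification for a categorical response.

    Each fold refits the whole pipeline on the training portion (so the
    precision estimate, when one is needed, is recomputed per fold and
    reused across the tau grid) and classifies the held-out samples by
    nearest centroid on the projected discriminant scores U = X V T,
    where T = (V' Sigma V)^{-1/2} is the canonical normalization (see
    :func:`sparsesir.metrics.canonical_normalize`).

    ``precision_factory``, when given, is called as
    ``factory(sigma_hat, n_train, X_train)`` on every training fold and
    must return a precision estimate for the whitening step; when it is
    None the fold covariance is inverted directly.
    """
    if data.response_kind != "categorical":
        raise ValueError("cv_select requires a categorical response")
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty tau grid")
    if K < 2:
        raise ValueError("need K >= 2 folds")
    labels, y_idx = np.unique(data.y, return_inverse=True)
    if np.bincount(y_idx).min() < K:
        raise ValueError("every class needs at least K samples for "
                         "stratified folds")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    errors = np.zeros((K, grid.size))
    zero_everywhere = True
    for k, (tr, te) in enumerate(skf.split(data.X, y_idx)):
        Xtr, ytr = data.X[tr], data.y[tr]
        if len(np.unique(ytr)) < len(labels):
            raise ValueError(f"class absent from training fold {k}")
        train = Dataset(X=Xtr, y=ytr, response_kind="categorical")
        slices = slice_response(ytr, kind="categorical")
        seed_est = compute_moments(train, slices)
        omega = None
        if precision_factory is not None:
            omega = precision_factory(seed_est.sigma_hat, train.n, Xtr)
        kernel = whitened_kernel(seed_est, omega=omega, d=d)
        center = seed_est.grand_mean
        Xte_c = data.X[te] - center
        Xtr_c = Xtr - center
        for i, tau in enumerate(grid):
            basis = solve_program(kernel, tau)
            if basis.s_tau > 0:
                zero_everywhere = False
            Vc = canonical_normalize(basis, seed_est.sigma_hat)
            u_tr = sufficient_predictors(Xtr_c, Vc)
            u_te = sufficient_predictors(Xte_c, Vc)
            pred = nearest_centroid(u_tr, ytr, u_te)
            errors[k, i] = misclassification_rate(pred, data.y[te])
    if zero_everywhere:
        raise ValueError("all candidates produced an all-zero basis")
    cv = errors.mean(axis=0)
    s_vals = np.zeros(grid.shape, dtype=int)
    tau_opt = _argmin_prefer_sparse(grid, cv)
    return TuningResult(grid=grid, scores=cv, s_values=s_vals,
                        tau_opt=tau_opt, criterion="cv")
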