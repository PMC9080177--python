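"""Inverse covariance estimation by constrained l1 minimization (CLIME).

When p >= n the sample covariance is singular and cannot be inverted to
whiten the SIR kernel.  CLIME estimates Omega = Sigma^{-1} by

    min ||Omega||_1  subject to  max_{k,l} |(Sigma_hat Omega - I)_{k,l}| <= lambda_1n,

which decouples into p independent linear programs, one per column
(column j targets the canonical basis vector e_j).  The raw solution is
not symmetric in general; the published symmetrization keeps, for every
pair (k, l), whichever of the two entries has smaller magnitude.

The constraint is elementwise: that is how the cited estimator is
defined and what makes the column decomposition valid.  (The max-row-l1
matrix norm convention used elsewhere in this package applies to the
group-Dantzig program, not here.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

logger = logging.getLogger(__name__)


@dataclass
class PrecisionEstimate:
    """CLIME solution and its symmetrized version."""

    omega_raw: np.ndarray
    omega_sym: np.ndarray
    lambda_1n: float
    c1: float | None = None


def default_lambda(n: int, p: int, c1: float) -> float:
    """Constraint level lambda_1n = c1 * sqrt(log(p) / n)."""
    if n < 1 or p < 2:
        raise ValueError("need n >= 1 and p >= 2")
    if not c1 > 0:
        raise ValueError("c1 must be positive")
    return float(c1) * float(np.sqrt(np.log(p) / n))


def clime_solve(sigma_hat: np.ndarray, lambda_1n: float) -> np.ndarray:
    """Solve the CLIME program column by column.

    Each column j solves the LP

        min ||w||_1  s.t.  ||Sigma_hat w - e_j||_inf <= lambda_1n

    via the standard positive/negative split w = w+ - w-.
    """
    S = np.asarray(sigma_hat, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("sigma_hat must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("sigma_hat must be symmetric")
    lam = float(lambda_1n)
    if lam < 0:
        raise ValueError("lambda_1n must be nonnegative")
    p = S.shape[0]
    A_ub = sparse.csr_matrix(np.block([[S, -S], [-S, S]]))
    c = np.ones(2 * p)
    omega = np.empty((p, p))
    for j in range(p):
        b_ub = np.full(2 * p, lam)
        b_ub[j] += 1.0
        b_ub[p + j] -= 1.0
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None),
                      method="highs")
        if res.status != 0:
            raise RuntimeError(
                f"CLIME column {j} LP failed (status {res.status}): "
                f"{res.message}")
        omega[:, j] = res.x[:p] - res.x[p:]
    return omega


def symmetrize(omega_raw: np.ndarray) -> np.ndarray:
    """Keep the smaller-magnitude entry of each (k,l)/(l,k) pair.

    Ties (equal magnitudes, possibly opposite signs) resolve to the
    (k, l) entry with k < l, matching the published indicator with its
    "<=" branch.
    """
    A = np.asarray(omega_raw, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("omega_raw must be square")
    picked = np.where(np.abs(A) <= np.abs(A.T), A, A.T)
    upper = np.triu(picked)
    return upper + np.triu(picked, 1).T


def select_c1(X: np.ndarray, grid=(0.5, 1.0, 2.0, 4.0), K: int = 5,
              seed: int = 0) -> float:
    """Choose the CLIME multiplier C1 by K-fold cross-validation.

    For each candidate, CLIME is fit on each training fold and scored by
    ||Sigma_hat_test @ Omega_hat_sym - I||_F on the held-out fold; the
    candidate with the smallest mean score wins (ties: the smallest
    multiplier, i.e. the least shrinkage).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2 * K:
        raise ValueError("too few samples for the requested fold count")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, K)
    scores = np.zeros(len(grid))
    eye = np.eye(p)
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        Xtr = X[train_idx] - X[train_idx].mean(axis=0)
        Xte = X[test_idx] - X[test_idx].mean(axis=0)
        S_tr = Xtr.T @ Xtr / len(train_idx)
        S_te = Xte.T @ Xte / len(test_idx)
        for i, c1 in enumerate(grid):
            lam = default_lambda(len(train_idx), p, c1)
            om = symmetrize(clime_solve(S_tr, lam))
            scores[i] += np.linalg.norm(S_te @ om - eye, ord="fro")
    best = int(np.argmin(scores))
    logger.info("select_c1: grid=%s mean scores=%s -> c1=%s",
                list(grid), list(scores / K), grid[best])
    return float(grid[best])


def save_precision(path, est: PrecisionEstimate) -> None:
    """Write the symmetrized estimate as a dense TSV matrix.

    The constraint level is kept in a header comment so a cached
    estimate can be matched to its tuning level when reloaded.
    """
    with open(path, "w") as fh:
        fh.write(f"# lambda_1n={est.lambda_1n!r}"
                 f" c1={'' if est.c1 is None else repr(est.c1)}\n")
        np.savetxt(fh, est.omega_sym, delimiter="\t")


def load_precision(path) -> PrecisionEstimate:
    """Reload a cached symmetrized CLIME estimate written by save_precision."""
    with open(path) as fh:
        header = fh.readline()
        omega = np.loadtxt(fh, delimiter="\t", ndmin=2)
    fields = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    c1 = float(fields["c1"]) if fields.get("c1") else None
    return PrecisionEstimate(omega_raw=omega.copy(), omega_sym=omega,
                             lambda_1n=float(fields["lambda_1n"]), c1=c1)


def estimate_precision(sigma_hat: np.ndarray, n: int,
                       c1: float | None = None,
                       lambda_1n: float | None = None,
                       X: np.ndarray | None = None,
                       seed: int = 0) -> PrecisionEstimate:
    """CLIME precision estimate with symmetrization.

    ``lambda_1n`` wins if given; otherwise it is c1 * sqrt(log p / n),
    with c1 chosen by cross-validation on ``X`` when not supplied.
    """
    p = sigma_hat.shape[0]
    if lambda_1n is None:
        if c1 is None:
            if X is None:
                raise ValueError("supply c1, lambda_1n, or X for CV")
            c1 = select_c1(X, seed=seed)
        lambda_1n = default_lambda(n, p, c1)
    omega_raw = clime_solve(sigma_hat, lambda_1n)
    omega_sym = symmetrize(omega_raw)
    return PrecisionEstimate(omega_raw=omega_raw, omega_sym=omega_sym,
                             lambda_1n=float(lambda_1n), c1=c1)
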