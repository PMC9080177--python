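"""The group-Dantzig program for a row-sparse central-subspace basis.

The estimator solves

    min_V sum_i ||v_i||_2   subject to   ||K Vtilde - V Lambda||_inf <= tau,

where K is the whitened kernel, (Vtilde, Lambda) its top-d eigenpairs,
v_i the rows of V, and ||.||_inf the maximum row l1-norm.  Because both
the objective and the constraint decompose over rows, the program splits
into p independent subproblems

    min ||v||_2  s.t.  sum_j |b_ij - lambda_j v_j| <= tau,      b_i = (K Vtilde)_i.

Row i is exactly zero iff ||b_i||_1 <= tau (zero is feasible precisely
then, and it is always optimal when feasible), which yields an exact
screening rule.  The surviving rows have a closed-form solution: writing
r = b - Lambda v, the subproblem is a weighted least-squares projection
onto the l1-ball of radius tau, whose KKT conditions give

    r_j(mu) = sign(b_j) * max(|b_j| - mu * lambda_j^2 / 2, 0)

with the multiplier mu > 0 fixed by sum_j |r_j(mu)| = tau — a piecewise
linear equation solved exactly by sorting the breakpoints.  Zeros are
exact, not thresholded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sir import WhitenedKernel, _fix_signs

logger = logging.getLogger(__name__)

#: reporting tolerance on row norms (screening makes zeros exact, so this
#: only guards against pathological round-off)
SUPPORT_TOL = 1e-8


@dataclass
class SparseBasis:
    """Row-sparse basis estimate with its support and certificates."""

    v_hat: np.ndarray
    tau: float
    support: np.ndarray
    s_tau: int
    orthonormalized: bool = False
    feasibility: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.v_hat.shape[0]

    @property
    def d(self) -> int:
        return self.v_hat.shape[1]


def row_targets(kernel: WhitenedKernel) -> np.ndarray:
    """Constraint targets B = K Vtilde (row i is b_i)."""
    return kernel.k_matrix @ kernel.v_tilde


def row_subproblem(b_i, lambda_tilde, tau: float) -> np.ndarray:
    """Exact minimizer of ||v||_2 s.t. sum_j |b_j - lambda_j v_j| <= tau.

    Returns the exact zero vector when ||b||_1 <= tau; otherwise the
    closed-form dual solution described in the module docstring.  For
    d = 1 this reduces to soft thresholding:
    v = sign(b) max(|b| - tau, 0) / lambda.
    """
    b = np.atleast_1d(np.asarray(b_i, dtype=float))
    lam = np.atleast_1d(np.asarray(lambda_tilde, dtype=float))
    if not tau > 0:
        raise ValueError("tau must be positive")
    if np.any(lam <= 0):
        raise ValueError("all eigenvalues lambda_j must be positive")
    ab = np.abs(b)
    if ab.sum() <= tau:
        return np.zeros_like(b)
    # r_j(mu) = sign(b_j) max(|b_j| - mu c_j, 0), c_j = lambda_j^2 / 2;
    # find mu with sum |r_j(mu)| = tau by scanning sorted breakpoints.
    c = lam ** 2 / 2.0
    breaks = ab / c
    order = np.argsort(breaks)
    s_ab, s_c = ab.sum(), c.sum()
    mu = None
    for idx in order:
        cand = (s_ab - tau) / s_c
        if cand <= breaks[idx] + 1e-15:
            mu = cand
            break
        s_ab -= ab[idx]
        s_c -= c[idx]
    if mu is None:  # pragma: no cover - unreachable since sum|r| -> 0
        mu = (ab / c).max()
    r = np.sign(b) * np.maximum(ab - mu * c, 0.0)
    return (b - r) / lam


def solve_program(kernel: WhitenedKernel, tau: float) -> SparseBasis:
    """Assemble the row-sparse basis from the p row subproblems.

    The support equals {i : ||b_i||_1 > tau} exactly; a feasibility
    certificate for the joint constraint is stored with the solution.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    B = row_targets(kernel)
    lam = kernel.lambda_tilde
    p, d = B.shape
    V = np.zeros((p, d))
    row_l1 = np.abs(B).sum(axis=1)
    active = np.flatnonzero(row_l1 > tau)
    for i in active:
        V[i] = row_subproblem(B[i], lam, tau)
    residual = float(np.abs(B - V * lam).sum(axis=1).max()) if p else 0.0
    feas = {"tau": float(tau), "max_row_l1_residual": residual,
            "feasible": bool(residual <= tau + 1e-7)}
    if not feas["feasible"]:
        logger.warning("solution violates the joint constraint: "
                       "residual %.3e > tau %.3e", residual, tau)
    row_norms = np.linalg.norm(V, axis=1)
    support = np.flatnonzero(row_norms > SUPPORT_TOL)
    return SparseBasis(v_hat=V, tau=float(tau), support=support,
                       s_tau=int(len(support)), orthonormalized=False,
                       feasibility=feas)


def gram_schmidt(basis: SparseBasis) -> SparseBasis:
    """Orthonormalize the basis columns without disturbing row sparsity.

    Gram-Schmidt mixes columns only, so zero rows stay exactly zero and
    the support is carried over unchanged.  Numerically dependent
    columns are dropped with a warning.  Column signs follow the
    largest-magnitude-entry-positive convention.
    """
    V = basis.v_hat
    if not np.any(V):
        raise ValueError("cannot orthonormalize an all-zero basis")
    cols = []
    scale = np.linalg.norm(V)
    for j in range(V.shape[1]):
        q = V[:, j].astype(float).copy()
        for qk in cols:
            q -= (qk @ q) * qk
        nrm = np.linalg.norm(q)
        if nrm <= 1e-12 * max(scale, 1.0):
            logger.warning("dropping linearly dependent column %d", j)
            continue
        cols.append(q / nrm)
    Q = _fix_signs(np.column_stack(cols))
    return SparseBasis(v_hat=Q, tau=basis.tau, support=basis.support.copy(),
                       s_tau=basis.s_tau, orthonormalized=True,
                       feasibility=dict(basis.feasibility))
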