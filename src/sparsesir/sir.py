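"""Slicing, moment estimation, and the whitened SIR eigen-system.

Sliced inverse regression rests on the fact that, under the linear
conditional mean condition, the centered inverse regression curve
E[X|Y] - E[X] lies in Sigma * span(V), where span(V) is the central
subspace.  Binning (slicing) the response and collecting the centered
slice means psi_h yields the kernel matrix

    M = sum_h (n_h / n) (xbar_h - xbar)(xbar_h - xbar)^T,

whose column space, after whitening by Sigma^{-1/2}, recovers the
central subspace through the top-d eigenvectors of
K = Sigma^{-1/2} M Sigma^{-1/2}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass
class Dataset:
    """Predictor matrix with its response.

    Parameters
    ----------
    X : (n, p) ndarray
        Samples in rows, predictors in columns.
    y : (n,) ndarray
        Response; real-valued for ``response_kind="continuous"``,
        arbitrary hashable labels for ``"categorical"``.
    response_kind : {"continuous", "categorical"}
    """

    X: np.ndarray
    y: np.ndarray
    response_kind: str = "continuous"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (samples x predictors)")
        n, p = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got n={n}")
        if p < 1:
            raise ValueError("need at least one predictor")
        if len(self.y) != n:
            raise ValueError(f"len(y)={len(self.y)} does not match n={n}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if self.response_kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        if self.response_kind == "continuous":
            yv = np.asarray(self.y, dtype=float)
            if not np.all(np.isfinite(yv)):
                raise ValueError("y contains missing or non-finite values")
            self.y = yv
        if len(np.unique(self.y)) < 2:
            raise ValueError("response must take at least 2 distinct values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class SliceStructure:
    """Partition of the samples induced by the response.

    ``assignment`` holds a 0-based slice index per sample; ``counts[h]``
    is the number of samples in slice h.  For a categorical response the
    slices are the classes (in sorted label order, recorded in
    ``labels``).
    """

    H: int
    assignment: np.ndarray
    counts: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.sum() != len(self.assignment):
            raise ValueError("slice counts do not sum to n")
        if np.any(self.counts < 1):
            raise ValueError("every slice must contain at least one sample")


@dataclass
class SeedEstimates:
    """Sample covariance and SIR kernel with slice bookkeeping."""

    sigma_hat: np.ndarray
    m_hat: np.ndarray
    grand_mean: np.ndarray
    slice_means: np.ndarray
    psi: np.ndarray  # H x p centered slice means
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    n: int = 0

    @property
    def H(self) -> int:
        return self.psi.shape[0]


@dataclass
class WhitenedKernel:
    """Whitened SIR kernel K = R M R and its leading eigen-system.

    R is the symmetric square root of the inverse covariance (either
    Sigma-hat^{-1} in the classical regime or the symmetrized CLIME
    estimate in the high-dimensional regime).  ``v_tilde`` holds the
    top-d orthonormal eigenvectors, ``lambda_tilde`` the corresponding
    (positive) eigenvalues.
    """

    k_matrix: np.ndarray
    v_tilde: np.ndarray
    lambda_tilde: np.ndarray
    d: int


def slice_response(y, H: int = 5, kind: str = "continuous") -> SliceStructure:
    """Partition the response into slices.

    Continuous responses are split into H contiguous groups of the order
    statistics with sizes as equal as possible (the first ``n mod H``
    slices get one extra sample); ties are broken by stable sort order.
    For a categorical response H is ignored and the slices are the
    distinct labels in sorted order.
    """
    y = np.asarray(y)
    n = len(y)
    if kind == "categorical":
        labels, assignment = np.unique(y, return_inverse=True)
        if len(labels) < 2:
            raise ValueError("categorical response needs >= 2 distinct labels")
        counts = np.bincount(assignment, minlength=len(labels))
        return SliceStructure(H=len(labels), assignment=assignment,
                              counts=counts, labels=labels)
    if kind != "continuous":
        raise ValueError(f"unknown response kind {kind!r}")
    if len(np.unique(y)) < 2:
        raise ValueError("continuous response needs >= 2 distinct values")
    if not 2 <= H <= n:
        raise ValueError(f"slice count H={H} must satisfy 2 <= H <= n={n}")
    order = np.argsort(y, kind="stable")
    base, extra = divmod(n, H)
    sizes = np.full(H, base, dtype=int)
    sizes[:extra] += 1
    if np.any(sizes < 1):
        raise ValueError("a slice would be empty; reduce H")
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.repeat(np.arange(H), sizes)
    return SliceStructure(H=H, assignment=assignment, counts=sizes)


def compute_moments(data: Dataset, slices: SliceStructure) -> SeedEstimates:
    """Sample covariance (divisor n) and SIR kernel from sliced data."""
    X = data.X
    n, p = X.shape
    if len(slices.assignment) != n:
        raise ValueError("slice structure inconsistent with data")
    xbar = X.mean(axis=0)
    Xc = X - xbar
    sigma_hat = Xc.T @ Xc / n
    sigma_hat = 0.5 * (sigma_hat + sigma_hat.T)

    H = slices.H
    slice_means = np.empty((H, p))
    for h in range(H):
        slice_means[h] = X[slices.assignment == h].mean(axis=0)
    psi = slice_means - xbar
    w = slices.counts / n
    m_hat = (psi * w[:, None]).T @ psi
    m_hat = 0.5 * (m_hat + m_hat.T)
    return SeedEstimates(sigma_hat=sigma_hat, m_hat=m_hat, grand_mean=xbar,
                         slice_means=slice_means, psi=psi,
                         counts=slices.counts.copy(), n=n)


def _sqrt_psd(A: np.ndarray, clip: float | None = None) -> np.ndarray:
    """Symmetric square root of a symmetric PSD matrix.

    Eigenvalues below ``clip`` are raised to ``clip`` (used for the
    CLIME estimate, which is positive definite only with high
    probability).
    """
    w, U = np.linalg.eigh(0.5 * (A + A.T))
    if clip is not None:
        if np.any(w < clip):
            logger.warning("clipping %d eigenvalue(s) below %.1e before sqrt",
                           int(np.sum(w < clip)), clip)
        w = np.maximum(w, clip)
    elif np.any(w < 0):
        w = np.maximum(w, 0.0)
    return (U * np.sqrt(w)) @ U.T


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def estimate_dimension(spectrum, cap: int | None = None,
                       threshold: float = 0.9) -> int:
    """Default structural-dimension rule.

    Returns the smallest d whose leading eigenvalues capture at least
    ``threshold`` of the total spectrum mass, capped at ``cap``
    (normally H - 1).  This is a pragmatic default; d should be supplied
    by the user whenever it is known.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if np.any(spectrum < -_EIG_TOL * max(1.0, abs(spectrum).max(initial=1.0))):
        raise ValueError("spectrum must be nonnegative")
    spectrum = np.maximum(spectrum, 0.0)
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: structural dimension undefined")
    frac = np.cumsum(np.sort(spectrum)[::-1]) / total
    d = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    if cap is not None:
        d = min(d, cap)
    return max(d, 1)


def whitened_kernel(seed: SeedEstimates, omega=None, d=None) -> WhitenedKernel:
    """Whitened kernel K = R M R and its top-d eigenpairs.

    Parameters
    ----------
    seed : SeedEstimates
    omega : PrecisionEstimate or None
        When None the sample covariance is inverted directly (classical
        p < n regime); otherwise R is the square root of the symmetrized
        CLIME estimate.
    d : int or None
        Structural dimension; None triggers the 90%-spectrum default
        capped at H - 1.

    Eigenvector signs are fixed by making the largest-magnitude
    coordinate of each column positive, for reproducibility.
    """
    M = seed.m_hat
    if omega is None:
        w, U = np.linalg.eigh(seed.sigma_hat)
        scale = max(w.max(initial=0.0), 0.0)
        if scale <= 0 or w.min() <= _EIG_TOL * scale:
            raise np.linalg.LinAlgError(
                "sample covariance is numerically singular; supply a CLIME "
                "precision estimate (p >= n regime)")
        R = (U / np.sqrt(w)) @ U.T
    else:
        omega_sym = getattr(omega, "omega_sym", omega)
        R = _sqrt_psd(np.asarray(omega_sym, dtype=float), clip=1e-10)
    K = R @ M @ R
    K = 0.5 * (K + K.T)

    evals, evecs = np.linalg.eigh(K)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    cap = seed.H - 1 if seed.H > 1 else 1
    if d is None:
        d = estimate_dimension(np.maximum(evals, 0.0), cap=cap)
    tol = _EIG_TOL * max(1.0, evals.max(initial=0.0))
    n_pos = int(np.sum(evals > tol))
    if d > n_pos:
        raise ValueError(
            f"d={d} exceeds the {n_pos} eigenvalue(s) above tolerance")
    V = _fix_signs(evecs[:, :d])
    return WhitenedKernel(k_matrix=K, v_tilde=V, lambda_tilde=evals[:d].copy(),
                          d=int(d))
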