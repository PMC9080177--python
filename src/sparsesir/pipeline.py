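"""End-to-end sparse SIR fit.

Pipeline: center (optionally scale) -> slice -> moments -> precision
estimate when the covariance cannot be inverted (p >= n or
ill-conditioned) -> whitened kernel -> tau selection (CV for categorical
responses, BIC for continuous) -> group-Dantzig solve -> Gram-Schmidt.
All intermediate artifacts are kept on the result for inspection, and
the run is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .clime import PrecisionEstimate, default_lambda, estimate_precision, select_c1
from .dantzig import SparseBasis, gram_schmidt, solve_program
from .selection import TuningResult, bic_select, cv_select, tau_grid
from .sir import Dataset, SeedEstimates, SliceStructure, WhitenedKernel, compute_moments, slice_response, whitened_kernel

logger = logging.getLogger(__name__)

#: condition-number threshold beyond which the sample covariance is
#: treated as numerically non-invertible even when p < n
COND_MAX = 1e10

#: the sample-covariance inverse is too noisy a whitener once p is a
#: sizable fraction of n; beyond this ratio the auto branch uses CLIME
DIM_RATIO = 0.5


@dataclass
class FitConfig:
    """Settings for :func:`fit_sparse_sir`.

    H : slice count for a continuous response (ignored for categorical,
        where the classes are the slices).  None applies the
        slice-size-of-20 rule of thumb, H = clip(n // 20, 5, 10).
    d : structural dimension; None selects it by the 90%-spectrum rule
        capped at H - 1.
    K : folds for categorical CV tuning.
    n_grid : size of the log-spaced tau grid.
    c1 : CLIME multiplier; None triggers 5-fold CV over {0.5, 1, 2, 4}.
    clime : "auto" (p at least half of n, or an ill-conditioned
        covariance), "always", or "never".
    tau : fixed constraint level, skipping tuning entirely.
    scale : divide centered columns by their standard deviation.
    """

    H: int | None = None
    d: int | None = None
    K: int = 5
    n_grid: int = 25
    c1: float | None = None
    clime: str = "auto"
    tau: float | None = None
    scale: bool = False
    seed: int = 0


@dataclass
class FitResult:
    """Fitted basis plus every intermediate artifact of the pipeline."""

    basis: SparseBasis
    basis_raw: SparseBasis
    slices: SliceStructure
    seed_est: SeedEstimates
    kernel: WhitenedKernel
    tuning: TuningResult | None
    precision: PrecisionEstimate | None
    branch: str
    config: FitConfig
    center: np.ndarray = None  # type: ignore[assignment]
    scale_: np.ndarray = None  # type: ignore[assignment]

    @property
    def support(self) -> np.ndarray:
        return self.basis.support

    @property
    def tau_opt(self) -> float:
        return self.basis.tau

    def transform(self, X: np.ndarray, canonical: bool = True) -> np.ndarray:
        """Sufficient predictors U = X V for new (raw-scale) data.

        By default the program's (un-orthonormalized) solution is used
        with the canonical discriminant normalization
        T = (V' Sigma V)^{-1/2}, so nearest-centroid classification on
        the scores behaves like discriminant analysis; ``canonical=False``
        projects onto the orthonormalized basis instead.
        """
        from .metrics import canonical_normalize

        Xs = (np.asarray(X, dtype=float) - self.center) / self.scale_
        if canonical:
            return Xs @ canonical_normalize(self.basis_raw,
                                            self.seed_est.sigma_hat)
        return Xs @ self.basis.v_hat

    def report(self) -> dict:
        """JSON-serializable run summary."""
        return {
            "n": int(self.seed_est.n),
            "p": int(self.basis.p),
            "H": int(self.slices.H),
            "d": int(self.kernel.d),
            "branch": self.branch,
            "tau_opt": float(self.basis.tau),
            "s_tau": int(self.basis.s_tau),
            "support": [int(i) for i in self.basis.support],
            "lambda_1n": (None if self.precision is None
                          else float(self.precision.lambda_1n)),
            "c1": (None if self.precision is None or self.precision.c1 is None
                   else float(self.precision.c1)),
            "feasibility": self.basis.feasibility,
            "config": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                       for k, v in asdict(self.config).items()},
        }


def _needs_clime(sigma_hat: np.ndarray, n: int, mode: str) -> bool:
    if mode == "always":
        return True
    if mode == "never":
        return False
    if mode != "auto":
        raise ValueError(f"unknown clime mode {mode!r}")
    p = sigma_hat.shape[0]
    if p >= DIM_RATIO * n:
        return True
    w = np.linalg.eigvalsh(sigma_hat)
    return w[0] <= 0 or w[-1] / w[0] > COND_MAX


def fit_sparse_sir(data: Dataset, config: FitConfig | None = None) -> FitResult:
    """Fit the coordinate-independent sparse SIR estimator."""
    config = config or FitConfig()
    center = data.X.mean(axis=0)
    if config.scale:
        sd = data.X.std(axis=0)
        zero = sd == 0
        if zero.any():
            logger.warning("%d constant column(s) left unscaled", zero.sum())
            sd = np.where(zero, 1.0, sd)
    else:
        sd = np.ones(data.p)
    Xs = (data.X - center) / sd
    work = Dataset(X=Xs, y=data.y, response_kind=data.response_kind)

    kind = data.response_kind
    if kind == "categorical":
        slices = slice_response(work.y, kind="categorical")
    else:
        H = config.H if config.H is not None else int(np.clip(work.n // 20, 5, 10))
        slices = slice_response(work.y, H=H, kind="continuous")
    seed_est = compute_moments(work, slices)

    precision = None
    c1 = config.c1
    if _needs_clime(seed_est.sigma_hat, work.n, config.clime):
        branch = "clime"
        if c1 is None:
            c1 = select_c1(Xs, seed=config.seed)
        lam = default_lambda(work.n, work.p, c1)
        precision = estimate_precision(seed_est.sigma_hat, work.n, c1=c1,
                                       lambda_1n=lam)
        logger.info("high-dimensional branch: CLIME with lambda_1n=%.4g "
                    "(c1=%.3g)", lam, c1)
    else:
        branch = "classical"
        logger.info("classical branch: direct inversion of the sample "
                    "covariance (p=%d, n=%d)", work.p, work.n)

    kernel = whitened_kernel(seed_est, omega=precision, d=config.d)

    tuning = None
    if config.tau is not None:
        tau_opt = float(config.tau)
    else:
        grid = tau_grid(kernel, config.n_grid)
        if kind == "categorical":
            factory = None
            if precision is not None:
                lam_c1 = c1

                def factory(sig, n_tr, X_tr, _c1=lam_c1):
                    return estimate_precision(
                        sig, n_tr, c1=_c1,
                        lambda_1n=default_lambda(n_tr, sig.shape[0], _c1))

            tuning = cv_select(work, grid, K=config.K, seed=config.seed,
                               d=kernel.d, precision_factory=factory)
        else:
            tuning = bic_select(kernel, seed_est, grid, work.n)
        tau_opt = tuning.tau_opt
    logger.info("selected tau = %.5g", tau_opt)

    basis_raw = solve_program(kernel, tau_opt)
    basis = gram_schmidt(basis_raw) if basis_raw.s_tau > 0 else basis_raw
    return FitResult(basis=basis, basis_raw=basis_raw, slices=slices,
                     seed_est=seed_est, kernel=kernel, tuning=tuning,
                     precision=precision, branch=branch, config=config,
                     center=center, scale_=sd)
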