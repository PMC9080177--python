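"""Synthetic generative designs with known truth.

Six designs are provided.  Three continuous-response regressions share
the AR(1) predictor covariance Sigma_ij = 0.5^{|i-j|} and a standard
normal error:

    m7  (linear, d=1):       y = (x1+x2+x3)/sqrt(3) + 2 eps
    m8  (single-index, d=1): y = 1 + exp{(x1+x2+x3)/sqrt(3)} + eps
    m9  (two-index, d=2):    y = (x1+x2+x3) / (0.5 + (x4+x5+1.5)^2) + 0.1 eps

Three categorical designs use a block covariance whose upper s x s
signal block is rho*J + (1-rho)*I (s = 20) and identity elsewhere:

    cat1: three classes, 30 samples each, common covariance; mean shifts
          of +1 on coordinates 1-10 (class 2) and -2 on 11-20 (class 3).
    cat2: same means, but class-specific covariances (signal block with
          rho = 0.9 | AR(1) with 0.5^{|i-j|} | identity).
    cat3: binary labels from a logistic forward model, Y ~ Bernoulli(
          expit(v'X)), with 10 nonzero coefficients drawn U(0.8, 1)
          fresh per replication.

For cat1 the true discriminant basis consists of the eigenvectors of
Sigma^{-1} M for the two nonzero eigenvalues, M being the between-class
covariance; cat2 reuses that construction with the pooled (average)
covariance, a reporting convention since LDA truth is not defined under
unequal covariances.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.special import expit

from .metrics import (
    misclassification_rate,
    nearest_centroid,
    projection_distance,
    selection_metrics,
    sufficient_predictors,
)
from .pipeline import FitConfig, fit_sparse_sir
from .sir import Dataset

logger = logging.getLogger(__name__)

MODEL_IDS = ("m7", "m8", "m9", "cat1", "cat2", "cat3")

#: size of the correlated signal block in the categorical designs
SIGNAL_BLOCK = 20
#: test-set size for categorical generalization error
TEST_SIZE = 900


@dataclass
class SimModelSpec:
    """One generative design with its truth (where fixed a priori)."""

    model_id: str
    n: int
    p: int
    d: int
    rho: float | None = None
    n_per_class: int | None = None
    true_basis: np.ndarray | None = None
    true_support: np.ndarray | None = None
    noise_law: str = "N(0,1)"

    @property
    def is_categorical(self) -> bool:
        return self.model_id.startswith("cat")


def ar1_cov(p: int, rho: float = 0.5) -> np.ndarray:
    i = np.arange(p)
    return rho ** np.abs(i[:, None] - i[None, :])


def block_cov(p: int, rho: float, s: int = SIGNAL_BLOCK) -> np.ndarray:
    """Signal block rho*J + (1-rho)*I on the first s coordinates, identity elsewhere."""
    if p < s:
        raise ValueError(f"p={p} too small for a {s}-variable signal block")
    sigma = np.eye(p)
    sigma[:s, :s] = rho * np.ones((s, s)) + (1 - rho) * np.eye(s)
    return sigma


def _cat_means(p: int) -> np.ndarray:
    mu = np.zeros((3, p))
    mu[1, :10] = 1.0
    mu[2, 10:20] = -2.0
    return mu


def true_directions(sigma: np.ndarray, class_means: np.ndarray,
                    priors=None) -> tuple[np.ndarray, np.ndarray]:
    """Population discriminant directions from a generalized eigenproblem.

    M = sum_k pi_k (mu_k - mu_bar)(mu_k - mu_bar)' and the basis is the
    eigenvectors of Sigma^{-1} M for the nonzero eigenvalues.  Entries
    that are numerically zero are rounded to exact zeros so the support
    is well defined.
    """
    sigma = np.asarray(sigma, dtype=float)
    mu = np.atleast_2d(np.asarray(class_means, dtype=float))
    K, p = mu.shape
    if priors is None:
        priors = np.full(K, 1.0 / K)
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()
    w = np.linalg.eigvalsh(sigma)
    if w.min() <= 0:
        raise np.linalg.LinAlgError("sigma must be positive definite")
    mu_bar = priors @ mu
    dev = mu - mu_bar
    M = (dev * priors[:, None]).T @ dev
    evals, evecs = eigh(M, sigma)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    tol = 1e-10 * max(evals.max(initial=0.0), 1.0)
    d = int(np.sum(evals > tol))
    if d == 0:
        return np.zeros((p, 0)), np.array([], dtype=int)
    V = evecs[:, :d]
    V = np.where(np.abs(V) > 1e-10 * np.abs(V).max(), V, 0.0)
    support = np.flatnonzero(np.linalg.norm(V, axis=1) > 0)
    return V, support


def model_spec(model_id: str, n: int | None = None, p: int | None = None,
               rho: float | None = None) -> SimModelSpec:
    """Build a design spec with its published defaults.

    Continuous models default to n=200, p=150 (m8 is commonly run at
    n=100 as the high-dimensional setting); cat1/cat2 default to 30
    samples per class at p=50; cat3 to n=100, p=50.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; "
                         f"valid ids: {', '.join(MODEL_IDS)}")
    if model_id in ("m7", "m8", "m9"):
        n = 200 if n is None else n
        p = 150 if p is None else p
        if model_id == "m9":
            if p < 5:
                raise ValueError("m9 needs p >= 5")
            V = np.zeros((p, 2))
            V[:3, 0] = 1.0
            V[3:5, 1] = 1.0
            d = 2
        else:
            if p < 3:
                raise ValueError(f"{model_id} needs p >= 3")
            V = np.zeros((p, 1))
            V[:3, 0] = 1.0
            d = 1
        support = np.flatnonzero(np.linalg.norm(V, axis=1) > 0)
        return SimModelSpec(model_id=model_id, n=n, p=p, d=d, rho=0.5,
                            true_basis=V, true_support=support,
                            noise_law="N(0,1)")

    rho = 0.5 if rho is None else rho
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    p = 50 if p is None else p
    if model_id in ("cat1", "cat2"):
        if p < SIGNAL_BLOCK:
            raise ValueError(f"{model_id} needs p >= {SIGNAL_BLOCK}")
        n_per_class = 30 if n is None else n // 3
        mu = _cat_means(p)
        if model_id == "cat1":
            sigma = block_cov(p, rho)
        else:
            # pooled covariance of the three class laws, by convention
            sigma = (block_cov(p, 0.9) + ar1_cov(p, 0.5) + np.eye(p)) / 3.0
        V, support = true_directions(sigma, mu)
        return SimModelSpec(model_id=model_id, n=3 * n_per_class, p=p, d=2,
                            rho=rho, n_per_class=n_per_class, true_basis=V,
                            true_support=support)
    # cat3: truth is drawn per replication
    if p < 10:
        raise ValueError("cat3 needs p >= 10")
    n = 100 if n is None else n
    return SimModelSpec(model_id="cat3", n=n, p=p, d=1, rho=rho,
                        true_basis=None, true_support=None,
                        noise_law="Bernoulli(logistic)")


def gen_continuous(spec: SimModelSpec, seed=None) -> tuple[Dataset, dict]:
    """Draw one continuous-response dataset with its truth."""
    if spec.model_id not in ("m7", "m8", "m9"):
        raise ValueError(f"{spec.model_id} is not a continuous design")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(ar1_cov(spec.p, 0.5))
    X = rng.standard_normal((spec.n, spec.p)) @ L.T
    eps = rng.standard_normal(spec.n)
    idx1 = (X[:, 0] + X[:, 1] + X[:, 2]) / np.sqrt(3.0)
    if spec.model_id == "m7":
        y = idx1 + 2.0 * eps
    elif spec.model_id == "m8":
        y = 1.0 + np.exp(idx1) + eps
    else:
        y = (X[:, 0] + X[:, 1] + X[:, 2]) / (
            0.5 + (X[:, 3] + X[:, 4] + 1.5) ** 2) + 0.1 * eps
    data = Dataset(X=X, y=y, response_kind="continuous")
    truth = {"basis": spec.true_basis.copy(), "support": spec.true_support.copy(),
             "d": spec.d}
    return data, truth


def _gen_cat_classes(mu, sigmas, sizes, rng) -> tuple[np.ndarray, np.ndarray]:
    blocks, labels = [], []
    for k, (m, S, nk) in enumerate(zip(mu, sigmas, sizes)):
        L = np.linalg.cholesky(S)
        blocks.append(m + rng.standard_normal((nk, len(m))) @ L.T)
        labels.append(np.full(nk, k))
    return np.vstack(blocks), np.concatenate(labels)


def gen_categorical(spec: SimModelSpec, seed=None,
                    n_override: int | None = None,
                    coef: np.ndarray | None = None) -> tuple[Dataset, dict]:
    """Draw one categorical dataset with its truth.

    ``n_override`` draws a different total sample size from the same law
    (used for independent test sets); class sizes stay equal for
    cat1/cat2 and cat3 samples from the marginal model.  For cat3 the
    logistic coefficient vector is drawn fresh unless ``coef`` pins it
    (as when drawing a test set from the same population as a training
    draw).
    """
    if not spec.is_categorical:
        raise ValueError(f"{spec.model_id} is not a categorical design")
    rng = np.random.default_rng(seed)
    p = spec.p
    if spec.model_id in ("cat1", "cat2"):
        total = n_override if n_override is not None else 3 * spec.n_per_class
        nk = total // 3
        sizes = [nk, nk, total - 2 * nk]
        mu = _cat_means(p)
        if spec.model_id == "cat1":
            sigmas = [block_cov(p, spec.rho)] * 3
        else:
            sigmas = [block_cov(p, 0.9), ar1_cov(p, 0.5), np.eye(p)]
        X, y = _gen_cat_classes(mu, sigmas, sizes, rng)
        truth = {"basis": spec.true_basis.copy(),
                 "support": spec.true_support.copy(), "d": spec.d}
    else:
        n = n_override if n_override is not None else spec.n
        # signal block clipped to p when p < 20 (10 coefficients still fit)
        sigma = block_cov(p, spec.rho, s=min(SIGNAL_BLOCK, p))
        L = np.linalg.cholesky(sigma)
        X = rng.standard_normal((n, p)) @ L.T
        if coef is None:
            v = np.zeros(p)
            v[:10] = rng.uniform(0.8, 1.0, size=10)
        else:
            v = np.asarray(coef, dtype=float).ravel()
        y = rng.binomial(1, expit(X @ v))
        if len(np.unique(y)) < 2:  # pragma: no cover - vanishingly unlikely
            y[0] = 1 - y[0]
        truth = {"basis": v[:, None], "support": np.flatnonzero(v), "d": 1}
    data = Dataset(X=X, y=y, response_kind="categorical")
    return data, truth


def generate(spec: SimModelSpec, seed=None, n_override: int | None = None,
             coef: np.ndarray | None = None):
    """Dispatch to the continuous or categorical generator."""
    if spec.is_categorical:
        return gen_categorical(spec, seed=seed, n_override=n_override,
                               coef=coef)
    if n_override is not None:
        spec = dataclasses.replace(spec, n=n_override)
    return gen_continuous(spec, seed=seed)


def _guarded_correlation(true_basis, est_basis, X) -> float:
    """Mean aligned |corr|, scoring zero for degenerate estimate columns."""
    U_true = X @ np.asarray(true_basis, dtype=float)
    U_est = X @ np.asarray(est_basis, dtype=float)
    d = U_true.shape[1]
    C = np.zeros((d, d))
    for j in range(d):
        for k in range(min(d, U_est.shape[1])):
            if U_true[:, j].std() == 0 or U_est[:, k].std() == 0:
                continue
            C[j, k] = abs(np.corrcoef(U_true[:, j], U_est[:, k])[0, 1])
    total, rows, cols = 0.0, set(range(d)), set(range(d))
    for _ in range(d):
        j, k = max(((j, k) for j in rows for k in cols),
                   key=lambda jk: C[jk[0], jk[1]])
        total += C[j, k]
        rows.discard(j)
        cols.discard(k)
    return total / d


def _replicate_once(spec: SimModelSpec, cfg: FitConfig, child_seed) -> dict:
    seeds = child_seed.spawn(3)
    data_seed, test_seed, fit_seed = seeds
    fit_int = int(fit_seed.generate_state(1)[0] % (2 ** 31))
    data, truth = generate(spec, seed=data_seed)
    cfg = dataclasses.replace(cfg, seed=fit_int,
                              d=cfg.d if cfg.d is not None else truth["d"])
    fit = fit_sparse_sir(data, cfg)
    tpr, fpr = selection_metrics(fit.support, truth["support"], spec.p)
    row = {"tpr": tpr, "fpr": fpr, "s_tau": fit.basis.s_tau,
           "tau_opt": fit.tau_opt}
    if spec.is_categorical:
        coef = truth["basis"][:, 0] if spec.model_id == "cat3" else None
        test, _ = generate(spec, seed=test_seed, n_override=TEST_SIZE,
                           coef=coef)
        if fit.basis.s_tau > 0:
            u_tr = fit.transform(data.X)
            u_te = fit.transform(test.X)
            pred = nearest_centroid(u_tr, data.y, u_te)
            row["msr"] = misclassification_rate(pred, test.y)
            try:
                row["delta"] = projection_distance(fit.basis.v_hat,
                                                   truth["basis"])
            except ValueError:
                row["delta"] = float(np.sqrt(truth["d"]))
        else:
            # empty basis: scores carry no information
            row["msr"] = 1.0 - np.max(np.bincount(
                np.unique(test.y, return_inverse=True)[1])) / len(test.y)
            row["delta"] = float(np.sqrt(truth["d"]))
    else:
        if fit.basis.s_tau > 0:
            Xc = data.X - data.X.mean(axis=0)
            row["corr"] = _guarded_correlation(truth["basis"],
                                               fit.basis.v_hat, Xc)
        else:
            row["corr"] = 0.0
    return row


def run_replications(spec: SimModelSpec, method_config: FitConfig | None = None,
                     reps: int = 20, seed: int = 0):
    """Repeat generate -> fit -> evaluate and tabulate the metrics.

    Child seeds are spawned deterministically from the master seed, so
    identical calls produce identical tables.  Returns
    ``(per_rep, summary)`` DataFrames; the summary has a ``mean`` row
    and an ``se`` row (standard error of the mean; absent for a single
    replication).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = method_config or FitConfig()
    children = np.random.SeedSequence(seed).spawn(reps)
    rows = []
    for r, child in enumerate(children):
        row = _replicate_once(spec, cfg, child)
        row["rep"] = r
        rows.append(row)
        logger.info("rep %d/%d: %s", r + 1, reps,
                    {k: round(v, 4) for k, v in row.items()
                     if isinstance(v, float)})
    per_rep = pd.DataFrame(rows).set_index("rep")
    metric_cols = [c for c in per_rep.columns if c != "tau_opt"]
    summary = pd.DataFrame({"mean": per_rep[metric_cols].mean()}).T
    if reps > 1:
        summary.loc["se"] = per_rep[metric_cols].std(ddof=1) / np.sqrt(reps)
    return per_rep, summary
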