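"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.optimize import minimize

from sparsesir.sir import WhitenedKernel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_kernel(rng, p=6, d=2, seedless=False) -> WhitenedKernel:
    """A well-formed whitened-kernel object with exact eigenpairs."""
    A = rng.standard_normal((p, p))
    K = A @ A.T / p
    w, U = np.linalg.eigh(K)
    w, U = w[::-1], U[:, ::-1]
    return WhitenedKernel(k_matrix=K, v_tilde=U[:, :d],
                          lambda_tilde=w[:d], d=d)


def monolithic_group_dantzig(B, lam, tau, tol=1e-12):
    """Whole-program convex solve of the row-sparse basis program.

    Independent oracle: minimize sum_i ||v_i||_2 subject to
    max_i sum_j |b_ij - lambda_j v_ij| <= tau, reformulated with slack
    variables T_ij >= |b_ij - lambda_j v_ij| so every constraint is
    linear and the objective is smooth; solved by SLSQP over the full
    p*d + p*d variable vector.  Returns (V, objective value).
    """
    B = np.atleast_2d(B)
    lam = np.asarray(lam, dtype=float)
    p, d = B.shape
    eps = 1e-12

    def unpack(z):
        return z[:p * d].reshape(p, d), z[p * d:].reshape(p, d)

    def obj(z):
        V, _ = unpack(z)
        return np.sqrt((V ** 2).sum(axis=1) + eps).sum()

    def jac(z):
        V, _ = unpack(z)
        nrm = np.sqrt((V ** 2).sum(axis=1) + eps)
        g = np.zeros_like(z)
        g[:p * d] = (V / nrm[:, None]).ravel()
        return g

    cons = []

    def make_upper(i, j):
        def f(z):
            V, T = unpack(z)
            return T[i, j] - (B[i, j] - lam[j] * V[i, j])
        return f

    def make_lower(i, j):
        def f(z):
            V, T = unpack(z)
            return T[i, j] + (B[i, j] - lam[j] * V[i, j])
        return f

    def make_budget(i):
        def f(z):
            _, T = unpack(z)
            return tau - T[i].sum()
        return f

    for i in range(p):
        cons.append({"type": "ineq", "fun": make_budget(i)})
        for j in range(d):
            cons.append({"type": "ineq", "fun": make_upper(i, j)})
            cons.append({"type": "ineq", "fun": make_lower(i, j)})

    z0 = np.concatenate([(B / lam).ravel(), np.zeros(p * d)])
    res = minimize(obj, z0, jac=jac, constraints=cons, method="SLSQP",
                   options={"maxiter": 1000, "ftol": tol})
    assert res.success, res.message
    V, _ = unpack(res.x)
    return V, np.linalg.norm(V, axis=1).sum()
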