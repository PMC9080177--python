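"""The group-Dantzig program: row subproblems, screening, orthonormalization."""

import numpy as np
import pytest

from sparsesir import gram_schmidt, row_subproblem, row_targets, solve_program
from sparsesir.sir import WhitenedKernel

from conftest import monolithic_group_dantzig, random_kernel


def exact_kernel(eigvals, p=None):
    """Kernel whose v_tilde are exact coordinate eigenvectors."""
    lam = np.asarray(eigvals, dtype=float)
    p = p or len(lam)
    K = np.zeros((p, p))
    K[:len(lam), :len(lam)] = np.diag(lam)
    d = int(np.sum(lam > 0))
    return WhitenedKernel(k_matrix=K, v_tilde=np.eye(p)[:, :d],
                          lambda_tilde=lam[:d], d=d)


class TestRowTargets:
    def test_exact_eigenvectors_give_b_equals_v_lambda(self, rng):
        k = random_kernel(rng, p=5, d=2)
        assert np.allclose(row_targets(k), k.v_tilde * k.lambda_tilde)

    def test_diagonal_case(self):
        k = exact_kernel([4.0, 1.0])
        k.v_tilde = np.array([[1.0], [0.0]])
        k.lambda_tilde = np.array([4.0])
        k.d = 1
        assert np.allclose(row_targets(k), [[4.0], [0.0]])

    def test_matches_direct_matmul(self, rng):
        k = random_kernel(rng, p=4, d=3)
        assert np.allclose(row_targets(k), k.k_matrix @ k.v_tilde)


class TestRowSubproblem:
    def test_zero_target_returns_exact_zero(self):
        v = row_subproblem(np.zeros(3), np.ones(3), tau=0.5)
        assert np.all(v == 0)

    def test_d1_soft_threshold_closed_form(self):
        assert row_subproblem([2.0], [1.0], 0.5) == pytest.approx([1.5])
        assert row_subproblem([-2.0], [2.0], 0.5) == pytest.approx([-0.75])
        assert np.all(row_subproblem([0.3], [1.0], 0.5) == 0)

    def test_d2_hand_instance(self):
        v = row_subproblem([3.0, 0.0], [1.0, 1.0], 1.0)
        assert np.allclose(v, [2.0, 0.0], atol=1e-10)

    @pytest.mark.parametrize("d", [2, 3])
    def test_matches_generic_convex_oracle(self, rng, d):
        for _ in range(5):
            b = rng.standard_normal(d) * 2
            lam = rng.uniform(0.5, 2.0, size=d)
            tau = 0.3 * np.abs(b).sum()
            v = row_subproblem(b, lam, tau)
            V_o, obj_o = monolithic_group_dantzig(b[None, :], lam, tau)
            assert np.linalg.norm(v) == pytest.approx(obj_o, abs=1e-5)
            # constraint is tight whenever the solution is nonzero
            assert np.abs(b - lam * v).sum() == pytest.approx(tau, abs=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError, match="tau"):
            row_subproblem([1.0], [1.0], 0.0)
        with pytest.raises(ValueError, match="lambda"):
            row_subproblem([1.0], [0.0], 0.5)


class TestSolveProgram:
    def test_tau_above_max_row_norm_gives_trivial_solution(self, rng):
        k = random_kernel(rng, p=6, d=2)
        tau_max = np.abs(row_targets(k)).sum(axis=1).max()
        basis = solve_program(k, tau_max * 1.0001)
        assert basis.s_tau == 0
        assert np.all(basis.v_hat == 0)

    def test_small_tau_recovers_nonsparse_eigenvectors(self, rng):
        k = random_kernel(rng, p=6, d=2)
        basis = solve_program(k, 1e-9)
        assert np.allclose(basis.v_hat, k.v_tilde, atol=1e-6)

    def test_support_equals_screening_rule_exactly(self, rng):
        k = random_kernel(rng, p=12, d=2)
        B = row_targets(k)
        for tau in (0.05, 0.2, 0.8):
            basis = solve_program(k, tau)
            expected = np.flatnonzero(np.abs(B).sum(axis=1) > tau)
            assert np.array_equal(basis.support, expected)
            zero_rows = np.setdiff1d(np.arange(12), expected)
            assert np.all(basis.v_hat[zero_rows] == 0)

    def test_support_non_increasing_in_tau(self, rng):
        k = random_kernel(rng, p=10, d=2)
        taus = np.geomspace(0.01, 2.0, 12)
        sizes = [solve_program(k, t).s_tau for t in taus]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_objective_matches_monolithic_convex_oracle(self, rng):
        k = random_kernel(rng, p=6, d=2)
        B = row_targets(k)
        tau = 0.4 * np.abs(B).sum(axis=1).max()
        basis = solve_program(k, tau)
        _, oracle_obj = monolithic_group_dantzig(B, k.lambda_tilde, tau)
        ours = np.linalg.norm(basis.v_hat, axis=1).sum()
        assert ours == pytest.approx(oracle_obj, abs=1e-5)

    def test_d1_equals_coordinatewise_soft_threshold(self, rng):
        k = random_kernel(rng, p=8, d=1)
        B = row_targets(k)[:, 0]
        lam = k.lambda_tilde[0]
        tau = 0.5 * np.abs(B).max()
        basis = solve_program(k, tau)
        expected = np.sign(B) * np.maximum(np.abs(B) - tau, 0) / lam
        assert np.allclose(basis.v_hat[:, 0], expected, atol=1e-8)

    def test_sign_flip_coordinate_independence(self, rng):
        k = random_kernel(rng, p=9, d=2)
        tau = 0.3 * np.abs(row_targets(k)).sum(axis=1).max()
        base = solve_program(k, tau)
        for signs in ([-1, 1], [1, -1], [-1, -1]):
            k2 = WhitenedKernel(k_matrix=k.k_matrix,
                                v_tilde=k.v_tilde * np.asarray(signs),
                                lambda_tilde=k.lambda_tilde, d=2)
            flipped = solve_program(k2, tau)
            assert np.array_equal(flipped.support, base.support)
            assert np.allclose(flipped.v_hat, base.v_hat * np.asarray(signs))
            assert np.isclose(np.linalg.norm(flipped.v_hat, axis=1).sum(),
                              np.linalg.norm(base.v_hat, axis=1).sum())

    def test_feasibility_certificate_stored(self, rng):
        k = random_kernel(rng, p=5, d=2)
        basis = solve_program(k, 0.3)
        assert basis.feasibility["feasible"]
        assert basis.feasibility["max_row_l1_residual"] <= 0.3 + 1e-7


class TestGramSchmidt:
    def test_orthonormal_input_unchanged_up_to_sign(self, rng):
        k = random_kernel(rng, p=6, d=2)
        basis = solve_program(k, 1e-9)
        q = gram_schmidt(basis)
        assert np.allclose(np.abs(q.v_hat.T @ basis.v_hat), np.eye(2),
                           atol=1e-6)

    def test_single_column_normalized_support_kept(self):
        k = exact_kernel([2.0], p=3)
        basis = solve_program(k, 0.5)
        q = gram_schmidt(basis)
        assert np.isclose(np.linalg.norm(q.v_hat), 1.0)
        assert np.array_equal(q.support, basis.support)

    def test_random_sparse_orthonormal_and_support_preserved(self, rng):
        k = random_kernel(rng, p=8, d=2)
        basis = solve_program(k, 0.3 * np.abs(row_targets(k)).sum(1).max())
        q = gram_schmidt(basis)
        assert np.allclose(q.v_hat.T @ q.v_hat, np.eye(q.v_hat.shape[1]),
                           atol=1e-10)
        nz = np.flatnonzero(np.linalg.norm(q.v_hat, axis=1) > 0)
        assert np.array_equal(nz, basis.support)

    def test_all_zero_basis_rejected(self, rng):
        k = random_kernel(rng, p=4, d=1)
        basis = solve_program(k, 100.0)
        with pytest.raises(ValueError, match="zero"):
            gram_schmidt(basis)
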