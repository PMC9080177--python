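"""Synthetic generative designs and the replication harness."""

import numpy as np
import pytest

from sparsesir import (
    FitConfig,
    gen_categorical,
    gen_continuous,
    model_spec,
    run_replications,
    true_directions,
)
from sparsesir.simulate import ar1_cov, block_cov, _cat_means


class TestSpecs:
    def test_unknown_model_rejected_with_listing(self):
        with pytest.raises(ValueError, match="cat3"):
            model_spec("nope")

    @pytest.mark.parametrize("mid,d,s", [("m7", 1, 3), ("m8", 1, 3),
                                         ("m9", 2, 5)])
    def test_continuous_truth_structure(self, mid, d, s):
        spec = model_spec(mid, n=50, p=30)
        assert spec.d == d
        assert len(spec.true_support) == s
        nz = np.flatnonzero(np.linalg.norm(spec.true_basis, axis=1) > 0)
        assert np.array_equal(nz, spec.true_support)

    def test_m9_truth_zero_beyond_first_five(self):
        spec = model_spec("m9", n=50, p=40)
        assert np.all(spec.true_basis[5:] == 0)

    def test_p_too_small_rejected(self):
        with pytest.raises(ValueError, match="p >= 5"):
            model_spec("m9", n=50, p=4)
        with pytest.raises(ValueError, match="p >= 20"):
            model_spec("cat1", p=10)


class TestContinuousGenerators:
    def test_ar1_covariance_recovered_empirically(self):
        # one large draw; entries within 3 standard errors of 0.5^{|i-j|}
        spec = model_spec("m7", n=100_000, p=5)
        data, _ = gen_continuous(spec, seed=0)
        emp = np.corrcoef(data.X.T)
        assert np.allclose(emp, ar1_cov(5, 0.5), atol=0.01)
        assert abs(data.X.mean()) < 0.01

    def test_m7_response_is_linear_in_index(self):
        spec = model_spec("m7", n=5_000, p=6)
        data, truth = gen_continuous(spec, seed=1)
        idx = data.X[:, :3].sum(axis=1) / np.sqrt(3)
        resid = data.y - idx
        # residual is the 2*eps term: mean 0, variance 4
        assert abs(resid.mean()) < 0.1
        assert abs(resid.var() - 4.0) < 0.3
        assert abs(np.corrcoef(resid, idx)[0, 1]) < 0.05

    def test_m8_response_matches_formula_support(self):
        spec = model_spec("m8", n=2_000, p=6)
        data, _ = gen_continuous(spec, seed=2)
        idx = data.X[:, :3].sum(axis=1) / np.sqrt(3)
        resid = data.y - 1.0 - np.exp(idx)
        assert abs(resid.mean()) < 0.1 and abs(resid.var() - 1.0) < 0.15

    def test_m9_rational_link(self):
        spec = model_spec("m9", n=2_000, p=7)
        data, _ = gen_continuous(spec, seed=3)
        idx = data.X[:, :3].sum(axis=1) / (
            0.5 + (data.X[:, 3] + data.X[:, 4] + 1.5) ** 2)
        resid = data.y - idx
        assert abs(resid.var() - 0.01) < 0.005

    def test_reproducible_from_seed(self):
        spec = model_spec("m7", n=50, p=10)
        a, _ = gen_continuous(spec, seed=5)
        b, _ = gen_continuous(spec, seed=5)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)


class TestCategoricalGenerators:
    def test_cat1_class_counts_and_support(self):
        spec = model_spec("cat1", p=30, rho=0.5)
        data, truth = gen_categorical(spec, seed=0)
        assert list(np.bincount(data.y)) == [30, 30, 30]
        assert set(truth["support"]) <= set(range(20))

    def test_cat1_between_class_kernel_rank_two(self):
        spec = model_spec("cat1", p=30, rho=0.5)
        assert spec.true_basis.shape[1] == 2

    def test_cat1_block_means_covariance_empirical(self):
        spec = model_spec("cat1", p=25, rho=0.5)
        n_each = 20_000
        data, _ = gen_categorical(spec, seed=1, n_override=3 * n_each)
        mu = _cat_means(25)
        for k in range(3):
            Xk = data.X[data.y == k]
            assert np.allclose(Xk.mean(0), mu[k], atol=0.04)
            assert np.allclose(np.cov(Xk.T), block_cov(25, 0.5), atol=0.06)

    def test_cat2_class_specific_covariances(self):
        spec = model_spec("cat2", p=25)
        data, _ = gen_categorical(spec, seed=2, n_override=30_000)
        X3 = data.X[data.y == 2]
        assert np.allclose(np.cov(X3.T), np.eye(25), atol=0.08)

    def test_cat3_ten_uniform_coefficients_fresh_each_draw(self):
        spec = model_spec("cat3", p=20, rho=0.5)
        _, t1 = gen_categorical(spec, seed=3)
        _, t2 = gen_categorical(spec, seed=4)
        for t in (t1, t2):
            v = t["basis"][:, 0]
            assert np.array_equal(t["support"], np.arange(10))
            assert np.all((v[:10] >= 0.8) & (v[:10] <= 1.0))
            assert np.all(v[10:] == 0)
        assert not np.array_equal(t1["basis"], t2["basis"])

    def test_cat3_test_draw_can_pin_coefficients(self):
        spec = model_spec("cat3", p=15, rho=0.5)
        _, truth = gen_categorical(spec, seed=5)
        _, t2 = gen_categorical(spec, seed=6, n_override=200,
                                coef=truth["basis"][:, 0])
        assert np.array_equal(t2["basis"], truth["basis"])

    def test_cat3_balanced_on_average(self):
        spec = model_spec("cat3", p=12, rho=0.5)
        data, _ = gen_categorical(spec, seed=7, n_override=20_000)
        assert abs(data.y.mean() - 0.5) < 0.03


class TestTrueDirections:
    def test_equal_means_give_empty_basis(self):
        V, sup = true_directions(np.eye(4), np.ones((3, 4)))
        assert V.shape == (4, 0) and len(sup) == 0

    def test_two_class_identity_covariance_is_mean_difference(self):
        mu = np.zeros((2, 4))
        mu[1, :2] = [2.0, -1.0]
        V, sup = true_directions(np.eye(4), mu)
        direction = V[:, 0] / np.linalg.norm(V[:, 0])
        target = (mu[1] - mu[0]) / np.linalg.norm(mu[1] - mu[0])
        assert np.allclose(np.abs(direction), np.abs(target), atol=1e-10)

    def test_cat1_parameters_solve_generalized_eigenproblem(self):
        p = 30
        sigma = block_cov(p, 0.5)
        mu = _cat_means(p)
        V, sup = true_directions(sigma, mu)
        assert V.shape[1] == 2
        priors = np.full(3, 1 / 3)
        dev = mu - priors @ mu
        M = (dev * priors[:, None]).T @ dev
        evals = np.array([(v @ M @ v) / (v @ sigma @ v) for v in V.T])
        resid = np.linalg.inv(sigma) @ M @ V - V * evals
        assert np.abs(resid).max() < 1e-8
        assert set(sup) <= set(range(20))

    def test_singular_sigma_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            true_directions(np.zeros((3, 3)), np.eye(3)[:2])


class TestRunReplications:
    cfg = FitConfig(c1=1.0)

    def test_single_rep_has_no_se_row(self):
        spec = model_spec("m7", n=100, p=15)
        per, summ = run_replications(spec, self.cfg, reps=1, seed=0)
        assert len(per) == 1
        assert "se" not in summ.index

    def test_same_seed_identical_tables(self):
        spec = model_spec("m7", n=100, p=15)
        a, sa = run_replications(spec, self.cfg, reps=2, seed=3)
        b, sb = run_replications(spec, self.cfg, reps=2, seed=3)
        assert a.equals(b) and sa.equals(sb)

    def test_adjacent_seeds_differ_same_schema(self):
        spec = model_spec("m7", n=100, p=15)
        a, _ = run_replications(spec, self.cfg, reps=2, seed=3)
        b, _ = run_replications(spec, self.cfg, reps=2, seed=4)
        assert list(a.columns) == list(b.columns)
        assert not a.equals(b)

    def test_majority_support_recovery_small_scale(self):
        spec = model_spec("m7", n=150, p=20)
        per, summ = run_replications(spec, self.cfg, reps=5, seed=1)
        assert summ.loc["mean", "tpr"] >= 0.8

    def test_categorical_reports_msr_and_delta(self):
        spec = model_spec("cat3", p=20, rho=0.5)
        per, summ = run_replications(spec, self.cfg, reps=2, seed=2)
        assert {"msr", "delta", "tpr", "fpr"} <= set(per.columns)
        assert per["msr"].between(0, 1).all()
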