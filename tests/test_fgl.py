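import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomanet import (ClassDataset, PenaltyConfig, empirical_covariance,
                       fgl_fit, fgl_objective, fused_prox, lambda_grid_fit)

from oracles import fgl_numeric_oracle, fused_prox_brute


def _random_covs(rng, p, D, n_obs=None):
    S = []
    for _ in range(D):
        B = rng.normal(size=(p, 3 * p))
        s = B @ B.T / (3 * p)
        S.append((s + s.T) / 2)
    return S


class TestEmpiricalCovariance:
    def test_single_feature_two_samples(self):
        ds = ClassDataset(
            [pd.DataFrame({"g": [-1.0, 1.0]}),
             pd.DataFrame({"g": [0.0, 2.0]})],
            ["a", "b"],
        )
        S = empirical_covariance(ds)
        assert S[0][0, 0] == pytest.approx(1.0)  # mean 0, 1/n denominator

    def test_whitened_data_has_unit_diagonal(self, rng):
        x = rng.standard_normal((40, 5))
        x = (x - x.mean(0)) / x.std(0)  # 1/n convention
        ds = ClassDataset([pd.DataFrame(x, columns=list("abcde"))] * 2,
                          ["c1", "c2"])
        S = empirical_covariance(ds)
        assert np.allclose(np.diag(S[0]), 1.0, atol=1e-12)

    def test_symmetric_psd(self, rng):
        x1 = pd.DataFrame(rng.standard_normal((10, 6)))
        x2 = pd.DataFrame(rng.standard_normal((8, 6)))
        S = empirical_covariance(ClassDataset([x1, x2], ["a", "b"]))
        for s in S:
            assert np.allclose(s, s.T)
            assert np.linalg.eigvalsh(s).min() >= -1e-10


class TestFusedProx:
    @pytest.mark.parametrize("a,lam1,lam2,expected", [
        ((3.0, 1.0), 0.0, 1.0, (2.0, 2.0)),   # fusion to the mean
        ((3.0, 1.0), 1.0, 1.0, (1.0, 1.0)),   # then soft-threshold
        ((3.0, 1.0), 1.0, 0.0, (2.0, 0.0)),   # plain soft-threshold
    ])
    def test_two_class_hand_examples(self, a, lam1, lam2, expected):
        assert fused_prox(a, lam1, lam2) == pytest.approx(expected)

    def test_unsupported_dimension(self):
        with pytest.raises(ValueError, match="D <= 4"):
            fused_prox([1.0] * 5, 0.1, 0.1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_in_three_dimensions(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 2, size=3)
        lam1 = float(rng.uniform(0, 1.5))
        lam2 = float(rng.uniform(0, 1.5))
        z = fused_prox(a, lam1, lam2)
        _, f_best = fused_prox_brute(a, lam1, lam2)

        def f(v):
            pen = lam1 * np.abs(v).sum()
            for i in range(3):
                for j in range(i + 1, 3):
                    pen += lam2 * abs(v[i] - v[j])
            return 0.5 * ((v - a) ** 2).sum() + pen

        assert f(z) <= f_best + 1e-8


class TestFGLFit:
    def test_identical_inputs_give_identical_precisions(self, rng):
        S = _random_covs(rng, 4, 1) * 2
        for lam2 in (0.0, 0.5, 5.0):
            ps = fgl_fit(S, [10, 10], PenaltyConfig(0.3, lam2), tol=1e-8,
                         max_iter=3000)
            assert np.abs(ps.Theta[0] - ps.Theta[1]).max() < 1e-8

    def test_identity_covariance_gives_diagonal_solution(self):
        S = [np.eye(4), np.eye(4)]
        ps = fgl_fit(S, [10, 12], PenaltyConfig(0.5, 0.2))
        for z, t in zip(ps.Z, ps.Theta):
            off = z - np.diag(np.diag(z))
            assert np.abs(off).max() == 0.0
            assert np.allclose(np.diag(t), 1.0, atol=1e-3)

    def test_objective_against_numeric_oracle(self, rng):
        """Small random instance agrees with direct convex minimization."""
        S = _random_covs(rng, 3, 2)
        n = [10, 15]
        cfg = PenaltyConfig(2.0, 1.0)
        ps = fgl_fit(S, n, cfg, tol=1e-10, max_iter=20000)
        T = fgl_numeric_oracle(S, n, cfg.lambda1, cfg.lambda2)
        assert abs(fgl_objective(ps.Theta, S, n, cfg)
                   - fgl_objective(T, S, n, cfg)) < 1e-4

    def test_large_lambda1_empties_offdiagonals(self, rng):
        S = _random_covs(rng, 5, 2)
        ps = fgl_fit(S, [20, 20], PenaltyConfig(1e3, 0.1))
        for z in ps.Z:
            off = z - np.diag(np.diag(z))
            assert np.abs(off).max() == 0.0

    def test_large_lambda2_fuses_classes(self, rng):
        S = _random_covs(rng, 5, 3)
        ps = fgl_fit(S, [20, 25, 30], PenaltyConfig(0.5, 1e3), tol=1e-8,
                     max_iter=5000)
        for d in range(3):
            for e in range(d + 1, 3):
                assert np.abs(ps.Z[d] - ps.Z[e]).max() <= 1e-6

    def test_zero_pattern_symmetric(self, rng):
        S = _random_covs(rng, 6, 2)
        ps = fgl_fit(S, [15, 18], PenaltyConfig(1.5, 0.3))
        for z in ps.Z:
            assert np.array_equal(z == 0, z.T == 0)

    def test_theta_positive_definite(self, rng):
        S = _random_covs(rng, 6, 3)
        ps = fgl_fit(S, [10, 10, 10], PenaltyConfig(1.0, 0.5))
        for t in ps.Theta:
            assert np.linalg.eigvalsh(t).min() > 0

    def test_asymmetric_covariance_rejected(self):
        S = [np.array([[1.0, 0.5], [0.2, 1.0]]), np.eye(2)]
        with pytest.raises(ValueError, match="symmetric"):
            fgl_fit(S, [5, 5], PenaltyConfig(0.1, 0.1))

    def test_nonconvergence_warns_and_flags(self, rng):
        S = _random_covs(rng, 4, 2)
        with pytest.warns(RuntimeWarning, match="converge"):
            ps = fgl_fit(S, [10, 10], PenaltyConfig(0.5, 0.2), max_iter=2)
        assert not ps.converged


class TestFGLObjective:
    def test_identity_value(self):
        S = [np.eye(4)] * 2
        T = [np.eye(4)] * 2
        val = fgl_objective(T, S, [10, 10], PenaltyConfig(0.0, 0.0))
        assert val == pytest.approx(80.0)  # 2 * 10 * (tr=4 - logdet=0)

    def test_lambda1_ignores_diagonal(self):
        S = [np.eye(3)] * 2
        T = [np.diag([1.0, 2.0, 3.0])] * 2
        a = fgl_objective(T, S, [5, 5], PenaltyConfig(0.0, 0.0))
        b = fgl_objective(T, S, [5, 5], PenaltyConfig(10.0, 0.0))
        assert a == b

    def test_identical_classes_zero_fusion_term(self, rng):
        S = _random_covs(rng, 3, 2)
        T = [np.eye(3) * 2.0] * 2
        a = fgl_objective(T, S, [5, 5], PenaltyConfig(0.3, 0.0))
        b = fgl_objective(T, S, [5, 5], PenaltyConfig(0.3, 100.0))
        assert a == b

    def test_non_pd_theta_rejected(self):
        S = [np.eye(2)] * 2
        T = [np.array([[1.0, 2.0], [2.0, 1.0]])] * 2
        with pytest.raises(np.linalg.LinAlgError):
            fgl_objective(T, S, [5, 5], PenaltyConfig(0.0, 0.0))


class TestLambdaGrid:
    def test_sparsity_monotone_in_lambda1(self, rng):
        x1 = pd.DataFrame(rng.standard_normal((60, 8)))
        x2 = pd.DataFrame(rng.standard_normal((50, 8)))
        ds = ClassDataset([x1, x2], ["a", "b"])
        fits, summary = lambda_grid_fit(ds, [1.0, 5.0, 20.0], [0.5],
                                        rho=50.0)
        for cls in ("a", "b"):
            counts = summary.sort_values("lambda1")[f"edges_{cls}"]
            assert (counts.diff().dropna() <= 0).all()

    def test_single_point_grid_matches_direct_fit(self, rng):
        x1 = pd.DataFrame(rng.standard_normal((30, 5)))
        x2 = pd.DataFrame(rng.standard_normal((25, 5)))
        ds = ClassDataset([x1, x2], ["a", "b"])
        fits, summary = lambda_grid_fit(ds, [2.0], [0.5])
        direct = fgl_fit(empirical_covariance(ds), ds.n_per_class,
                         PenaltyConfig(2.0, 0.5))
        assert len(summary) == 1
        assert np.allclose(fits[(2.0, 0.5)].Theta[0], direct.Theta[0])

    def test_summary_has_one_row_per_grid_point(self, rng):
        x1 = pd.DataFrame(rng.standard_normal((30, 4)))
        x2 = pd.DataFrame(rng.standard_normal((30, 4)))
        ds = ClassDataset([x1, x2], ["a", "b"])
        _, summary = lambda_grid_fit(ds, [1.0, 2.0], [0.1, 0.2, 0.3])
        assert len(summary) == 6
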