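"""Proximal operators, ADMM solver behaviour and baseline estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcnet import (
    ADMMState,
    SolverConfig,
    TimeSeriesMatrix,
    corr_fc,
    effective_objective,
    lr_mvrc,
    mvrc,
    pcorr_fc,
    soft_threshold,
    svt,
    symmetrize_abs,
    unit_normalize,
    update_w,
)
from fcnet.matrices import DegenerateInputError, RegressionWeights

from _oracles import dys_solve, random_instance

HIGH_ACCURACY = dict(tol=1e-13, max_iter=12000, rho=1.005)


class TestSoftThreshold:
    @pytest.mark.parametrize("v,alpha,expected", [
        (1.2, 0.5, 0.7),
        (-0.3, 0.5, 0.0),
        (-2.0, 0.5, -1.5),
    ])
    def test_scalar_closed_form(self, v, alpha, expected):
        assert soft_threshold(v, alpha) == pytest.approx(expected)

    def test_alpha_zero_is_identity(self, rng):
        m = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(soft_threshold(m, 0.0), m)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)

    @given(st.floats(-50, 50), st.floats(0, 10))
    def test_shrinks_towards_zero_by_at_most_alpha(self, v, alpha):
        out = soft_threshold(v, alpha)
        assert abs(out) <= abs(v) + 1e-12
        assert abs(v - out) <= alpha + 1e-12
        assert out * v >= 0  # never flips sign


class TestSVT:
    def test_identity_spectrum_shrunk(self):
        out = svt(np.eye(2), 0.4)
        np.testing.assert_allclose(out, 0.6 * np.eye(2), atol=1e-12)

    def test_diagonal_rank_drop(self):
        out = svt(np.diag([3.0, 1.0]), 2.0)
        np.testing.assert_allclose(out, np.diag([1.0, 0.0]), atol=1e-12)
        assert np.linalg.matrix_rank(out, tol=1e-10) == 1

    def test_alpha_zero_identity(self, rng):
        m = rng.normal(size=(5, 5))
        assert np.abs(svt(m, 0.0) - m).max() < 1e-10

    def test_singular_values_are_soft_thresholded(self, rng):
        m = rng.normal(size=(6, 4))
        alpha = 0.8
        s_in = np.linalg.svd(m, compute_uv=False)
        s_out = np.linalg.svd(svt(m, alpha), compute_uv=False)
        np.testing.assert_allclose(s_out, np.maximum(0.0, s_in - alpha), atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svt(np.array([[np.inf, 0.0], [0.0, 1.0]]), 0.1)


class TestWUpdate:
    def test_orthonormal_columns_closed_form(self):
        # X^T X = I, splits and multipliers zero, beta1=beta2=1:
        # pre-zeroing solution is I/3, whose off-diagonal part is zero.
        x = TimeSeriesMatrix(np.eye(4)[:, :3], normalized=True)
        state = ADMMState.cold_start(3, 1.0)
        w = update_w(x, state)
        np.testing.assert_allclose(w, np.zeros((3, 3)), atol=1e-12)

    def test_matches_independent_linear_solve(self, rng):
        x = TimeSeriesMatrix(rng.normal(size=(8, 4)))
        state = ADMMState.cold_start(4, 0.0)
        state.beta1, state.beta2 = 0.7, 1.3
        state.Z1 = rng.normal(size=(4, 4))
        state.Z2 = rng.normal(size=(4, 4))
        state.Y1 = rng.normal(size=(4, 4))
        state.Y2 = rng.normal(size=(4, 4))
        w = update_w(x, state)
        g = x.values.T @ x.values
        expected = np.linalg.solve(
            g + (state.beta1 + state.beta2) * np.eye(4),
            g + state.beta1 * state.Z1 + state.Y1
            + state.beta2 * state.Z2 + state.Y2,
        )
        np.fill_diagonal(expected, 0.0)
        assert np.abs(w - expected).max() < 1e-10
        assert np.all(np.diag(w) == 0.0)


def _normalized(seed, t=20, n=5):
    return TimeSeriesMatrix(random_instance(seed, t=t, n=n), normalized=True)


class TestLrMvrc:
    def test_requires_normalized_input(self, rng):
        ts = TimeSeriesMatrix(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="normalize"):
            lr_mvrc(ts, SolverConfig())

    def test_dominant_l1_penalty_zeroes_the_solution(self):
        x = _normalized(0)
        gram = x.values.T @ x.values
        mu1 = 10.0 * np.abs(gram - np.diag(np.diag(gram))).max()
        w, _ = lr_mvrc(x, SolverConfig(mu1=mu1, mu2=0.0, **HIGH_ACCURACY))
        assert np.abs(w.values).max() < 1e-8

    def test_unpenalized_limit_matches_direct_minimizer(self):
        # mu1 = mu2 = 0: the ADMM should land on the least-squares solution
        # with zero diagonal, independently found by projected splitting.
        x = _normalized(3, t=10, n=5)
        w, rep = lr_mvrc(x, SolverConfig(mu1=0.0, mu2=0.0, **HIGH_ACCURACY))
        w_o, obj_o = dys_solve(x.values, 0.0, 0.0)
        obj = effective_objective(x, w.values, 0.0, 0.0)
        assert rep.converged
        assert abs(obj - obj_o) / obj_o < 1e-3
        assert np.abs(w.values - w_o).max() < 0.05

    @pytest.mark.parametrize("seed,mu1,mu2", [(11, 0.1, 0.1), (12, 0.05, 0.3)])
    def test_effective_objective_matches_convex_oracle(self, seed, mu1, mu2):
        x = _normalized(seed, t=12, n=4)
        cfg = SolverConfig(mu1=mu1, mu2=mu2, **HIGH_ACCURACY)
        w, _ = lr_mvrc(x, cfg)
        s = cfg.prox_factor
        obj = effective_objective(x, w.values, s * mu1, s * mu2)
        _, obj_o = dys_solve(x.values, s * mu1, s * mu2)
        assert abs(obj - obj_o) / obj_o < 1e-3

    def test_residuals_converge_on_well_conditioned_instances(self):
        for seed in (0, 1, 2):
            x = _normalized(seed)
            w, rep = lr_mvrc(x, SolverConfig())
            assert rep.converged and rep.iterations < 500
            assert max(rep.final_residuals) / max(1.0, np.linalg.norm(w.values)) < 1e-6

    def test_sparsity_nondecreasing_in_l1_weight(self):
        x = _normalized(5, t=20, n=6)
        counts = []
        for mu1 in (0.01, 0.1, 0.5, 2.0):
            w, _ = lr_mvrc(x, SolverConfig(mu1=mu1, mu2=0.1, tol=1e-10, max_iter=2000))
            counts.append(int(np.sum(np.abs(w.values) < 1e-8)))
        assert counts == sorted(counts)

    def test_rank_nonincreasing_in_nuclear_weight(self):
        x = _normalized(5, t=20, n=6)
        ranks = []
        for mu2 in (0.01, 0.1, 0.5, 2.0):
            _, rep = lr_mvrc(x, SolverConfig(mu1=0.1, mu2=mu2, tol=1e-10))
            z2 = rep.final_state.Z2
            sv = np.linalg.svd(z2, compute_uv=False)
            ranks.append(int(np.sum(sv > 1e-8 * max(sv[0], 1e-300))))
        assert ranks == sorted(ranks, reverse=True)

    def test_objective_trace_recorded_and_diag_zero(self):
        x = _normalized(7)
        w, rep = lr_mvrc(x, SolverConfig())
        assert len(rep.objective_trace) == rep.iterations
        assert np.all(np.diag(w.values) == 0.0)


class TestMvrc:
    def test_zero_penalties_match_lr_mvrc(self):
        x = _normalized(4, t=15, n=5)
        cfg = SolverConfig(mu1=0.0, mu2=0.0, **HIGH_ACCURACY)
        w_lr, _ = lr_mvrc(x, cfg)
        w_en, _ = mvrc(x, 0.0, 0.0, cfg)
        assert np.abs(w_lr.values - w_en.values).max() < 1e-6

    def test_elastic_net_objective_matches_convex_oracle(self):
        x = _normalized(6, t=12, n=4)
        cfg = SolverConfig(**HIGH_ACCURACY)
        lam1, lam2 = 0.1, 0.2
        w, _ = mvrc(x, lam1, lam2, cfg)
        s = cfg.prox_factor
        obj = effective_objective(x, w.values, s * lam1, 0.0, frob_weight=s * lam2)
        _, obj_o = dys_solve(x.values, s * lam1, 0.0, frob=s * lam2)
        assert abs(obj - obj_o) / obj_o < 1e-3

    def test_dominant_l1_zeroes_solution(self):
        x = _normalized(2)
        w, _ = mvrc(x, 50.0, 0.1, SolverConfig(**HIGH_ACCURACY))
        assert np.abs(w.values).max() < 1e-8

    def test_negative_weights_rejected(self):
        x = _normalized(0)
        with pytest.raises(ValueError):
            mvrc(x, -1.0, 0.0)


class TestSymmetrizeAbs:
    def test_hand_example(self):
        w = RegressionWeights(np.array([[0.0, 2.0], [-4.0, 0.0]]))
        a = symmetrize_abs(w)
        np.testing.assert_allclose(a.values, [[0.0, 3.0], [3.0, 0.0]])

    def test_fixed_point_on_symmetric_nonnegative(self, rng):
        m = np.abs(rng.normal(size=(4, 4)))
        m = (m + m.T) * (1 - np.eye(4))
        a = symmetrize_abs(RegressionWeights(m))
        np.testing.assert_allclose(a.values, m, atol=1e-12)

    def test_transpose_invariance(self, rng):
        m = rng.normal(size=(5, 5)) * (1 - np.eye(5))
        a1 = symmetrize_abs(RegressionWeights(m))
        a2 = symmetrize_abs(RegressionWeights(m.T))
        np.testing.assert_allclose(a1.values, a2.values, atol=1e-15)


class TestCorrPcorr:
    def test_perfect_and_flipped_correlation(self, rng):
        c = rng.normal(size=20)
        x = TimeSeriesMatrix(np.column_stack([c, 2 * c + 0.0, -c]))
        a = corr_fc(x)
        assert a.values[0, 1] == pytest.approx(1.0)
        assert a.values[0, 2] == pytest.approx(1.0)  # negative flipped

    def test_orthogonal_zero_mean_columns_uncorrelated(self):
        t = np.arange(8.0)
        c1 = np.cos(2 * np.pi * t / 8)
        c2 = np.sin(2 * np.pi * t / 8)
        a = corr_fc(TimeSeriesMatrix(np.column_stack([c1, c2])))
        assert abs(a.values[0, 1]) < 1e-12

    def test_constant_column_rejected(self):
        x = TimeSeriesMatrix(np.column_stack([np.arange(5.0), np.ones(5)]),
                             ["v", "flat"])
        with pytest.raises(DegenerateInputError, match="flat"):
            corr_fc(x)

    def test_partial_correlation_removes_mediated_link(self, rng):
        # Precision matrix with Theta_12 = 0: variables 1 and 2 are linked
        # only through variable 3; build data with exactly that covariance.
        theta = np.array([[2.0, 0.0, 0.8], [0.0, 2.0, 0.9], [0.8, 0.9, 2.0]])
        cov = np.linalg.inv(theta)
        z = rng.normal(size=(60, 3))
        z -= z.mean(axis=0)
        zc = np.cov(z, rowvar=False)
        whiten = np.linalg.inv(np.linalg.cholesky(zc))
        x = z @ whiten.T @ np.linalg.cholesky(cov).T
        a = pcorr_fc(TimeSeriesMatrix(x))
        assert a.values[0, 1] < 1e-8
        # and the direct links survive
        assert a.values[0, 2] > 0.1 and a.values[1, 2] > 0.1

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(77)
        x = TimeSeriesMatrix(rng.normal(size=(2000, 4)))
        a = pcorr_fc(x)
        off = a.values[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_bivariate_partial_equals_marginal(self, rng):
        x = TimeSeriesMatrix(rng.normal(size=(40, 2)) @ np.array([[1.0, 0.4], [0.0, 1.0]]))
        ap = pcorr_fc(x)
        ac = corr_fc(x)
        assert abs(ap.values[0, 1] - ac.values[0, 1]) < 1e-9
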