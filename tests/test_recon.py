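"""Sparse reconstruction: shrink operator, ISTA, reweighted Lp solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from bltmds import recon as rc


def coordinate_descent_oracle(A, b, lam, nonnegative=True, tol=1e-12,
                              max_sweeps=20000):
    """Exact per-coordinate minimisation of 1/2||Ax-b||^2 + sum lam_i |x_i|.

    Independent oracle: cyclic coordinate descent with the closed-form
    single-coordinate solution, run to stationarity.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (A.shape[1],))
    x = np.zeros(A.shape[1])
    col_sq = np.einsum("ij,ij->j", A, A)
    r = b - A @ x
    for _ in range(max_sweeps):
        delta = 0.0
        for i in range(A.shape[1]):
            if col_sq[i] == 0:
                continue
            rho = A[:, i] @ r + col_sq[i] * x[i]
            if nonnegative:
                xi = max(rho - lam[i], 0.0) / col_sq[i]
            else:
                xi = np.sign(rho) * max(abs(rho) - lam[i], 0.0) / col_sq[i]
            if xi != x[i]:
                r = r - A[:, i] * (xi - x[i])
                delta = max(delta, abs(xi - x[i]))
                x[i] = xi
        if delta < tol:
            break
    return x


class TestShrink:
    @pytest.mark.parametrize(
        "a,z,nonneg,expected",
        [
            (2.0, 0.5, True, 1.5),
            (0.3, 0.5, True, 0.0),
            (-2.0, 0.5, False, -1.5),
            (-2.0, 0.5, True, 0.0),
            (0.0, 0.0, True, 0.0),
        ],
    )
    def test_values(self, a, z, nonneg, expected):
        assert rc.shrink(a, z, nonneg) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            rc.shrink(1.0, -0.1)

    @given(
        a=hst.floats(min_value=-100, max_value=100),
        z=hst.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_two_sided_is_odd_and_contractive(self, a, z):
        s = float(rc.shrink(a, z, nonnegative=False))
        assert s == pytest.approx(-float(rc.shrink(-a, z, nonnegative=False)))
        assert abs(s) <= abs(a)


class TestIsta:
    def test_one_dimensional_closed_form(self):
        """min 1/2 (s-1)^2 + 0.5 s over s >= 0 has solution s = 0.5."""
        r = rc.ista(np.array([[1.0]]), np.array([1.0]), 0.5)
        assert r.S[0] == pytest.approx(0.5, abs=1e-6)

    def test_unregularized_limit(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((8, 8)) + 4 * np.eye(8)
        b = rng.standard_normal(8)
        cfg = rc.ReconConfig(nonnegative=False, inner_iters=50000, rel_tol=1e-12)
        r = rc.ista(A, b, 0.0, cfg)
        assert np.allclose(r.S, np.linalg.solve(A, b), atol=1e-6)

    def test_matches_coordinate_descent_oracle(self):
        rng = np.random.default_rng(123)
        A = rng.standard_normal((30, 60))
        b = rng.standard_normal(30)
        lam = 0.1
        cfg = rc.ReconConfig(inner_iters=20000, rel_tol=1e-10)
        r = rc.ista(A, b, lam, cfg)
        x_star = coordinate_descent_oracle(A, b, lam)
        f = rc._l1_objective
        assert f(A, b, r.S, np.full(60, lam)) <= (
            f(A, b, x_star, np.full(60, lam)) + 1e-6
        )

    def test_monotone_descent(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((20, 40))
        b = rng.standard_normal(20)
        r = rc.ista(A, b, 0.05)
        d = np.diff(r.objective_trace)
        assert np.all(d <= 1e-12 * np.maximum(np.abs(r.objective_trace[:-1]), 1))

    def test_step_bound_violation_rejected(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((10, 10))
        L = rc.spectral_norm_sq(A)
        with pytest.raises(ValueError, match="step size"):
            rc.ista(A, np.ones(10), 0.1, rc.ReconConfig(xi=10.0 / L))

    def test_fixed_point_residual(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((25, 50))
        b = rng.standard_normal(25)
        cfg = rc.ReconConfig(rel_tol=1e-8, inner_iters=30000)
        r = rc.ista(A, b, 0.2, cfg)
        L = rc.spectral_norm_sq(A, seed=cfg.seed)
        step = 2 * 0.495 / L
        S = r.S
        fp = rc.shrink(S - step * (A.T @ (A @ S - b)), step * 0.2)
        assert np.linalg.norm(fp - S) <= 1e-6 * max(np.linalg.norm(S), 1.0)

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(11)
        A = rng.standard_normal((15, 30))
        b = rng.standard_normal(15)
        r = rc.ista(A, b, 0.01)
        assert np.all(r.S >= 0)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((20, 35))
        b = rng.standard_normal(20)
        r1 = rc.ista(A, b, 0.1)
        r2 = rc.ista(A, b, 0.1)
        assert np.array_equal(r1.S, r2.S)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rc.ista(np.array([[np.nan]]), np.array([1.0]), 0.1)


class TestObjectiveValue:
    def test_zero_solution(self):
        b = np.array([3.0, 4.0])
        A = np.eye(2)
        assert rc.objective_value(A, b, np.zeros(2), 1.0, 0.5) == pytest.approx(12.5)

    def test_tau_zero_pure_fit(self):
        A = np.eye(2)
        S = np.array([1.0, 2.0])
        assert rc.objective_value(A, np.zeros(2), S, 0.0, 0.5) == pytest.approx(2.5)

    def test_worked_example(self):
        val = rc.objective_value(
            np.array([[1.0]]), np.array([1.0]), np.array([0.5]), 1.0, 0.5
        )
        assert val == pytest.approx(0.125 + np.sqrt(0.5), rel=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            rc.objective_value(np.eye(2), np.zeros(2), np.zeros(2), 1.0, 1.5)


class TestNcsra:
    def test_single_outer_reduces_to_ista(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((20, 40))
        b = rng.standard_normal(20)
        zeta = 0.05
        cfg = rc.ReconConfig(zeta=zeta, outer_iters=1)
        r_out = rc.ncsra(A, b, cfg)
        r_ista = rc.ista(A, b, zeta, cfg)
        assert np.array_equal(r_out.S, r_ista.S)

    def test_exact_recovery_regime(self):
        """3-sparse non-negative signal from noise-free 60x200 system."""
        rng = np.random.default_rng(42)
        A = rng.standard_normal((60, 200))
        S_true = np.zeros(200)
        S_true[[10, 80, 150]] = [1.0, 2.0, 1.5]
        b = A @ S_true
        res = rc.ncsra(A, b)
        support = set(np.nonzero(res.S > 1e-6 * res.S.max())[0])
        assert support >= {10, 80, 150}
        err = np.linalg.norm(res.S - S_true) / np.linalg.norm(S_true)
        assert err <= 1e-3

    def test_lp_objective_non_increasing_across_outer(self):
        rng = np.random.default_rng(42)
        A = rng.standard_normal((60, 200))
        S_true = np.zeros(200)
        S_true[[10, 80, 150]] = [1.0, 2.0, 1.5]
        b = A @ S_true
        cfg = rc.ReconConfig()
        zeta = 1e-3 * np.max(np.abs(A.T @ b))
        objs = []
        S = np.zeros(200)
        for outer in range(cfg.outer_iters):
            if outer == 0:
                lam = np.full(200, zeta)
            else:
                lam = zeta * cfg.p * np.minimum(
                    (np.abs(S) + cfg.eps) ** (cfg.p - 1.0), cfg.weight_cap
                )
            S = rc.ista(A, b, lam, cfg, x0=S).S
            objs.append(rc.objective_value(A, b, S, zeta, cfg.p))
        assert all(objs[i + 1] <= objs[i] + 1e-12 for i in range(len(objs) - 1))

    def test_paper_literal_weights_flag(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((20, 50))
        b = A @ np.abs(rng.standard_normal(50)) * 0.1
        r1 = rc.ncsra(A, b, rc.ReconConfig(outer_iters=2))
        r2 = rc.ncsra(
            A, b, rc.ReconConfig(outer_iters=2, paper_literal_weights=True)
        )
        assert not np.array_equal(r1.S, r2.S)

    def test_determinism(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((30, 70))
        b = rng.standard_normal(30)
        assert np.array_equal(rc.ncsra(A, b).S, rc.ncsra(A, b).S)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rc.ReconConfig(p=1.0)
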