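"""Jacobians, Routh-Hurwitz criteria and Lyapunov / diagonal-stability checks."""

import numpy as np
import pytest

import seats
from seats import (
    ModelParameters,
    ParameterError,
    animosity_free_equilibrium,
    basic_reproduction_number,
    certify_endemic_global_stability,
    characteristic_polynomial,
    classify_local_stability,
    dfe_lyapunov_derivative,
    dfe_lyapunov_value,
    endemic_equilibrium,
    is_diagonally_stable,
    is_vl_stable_2x2,
    jacobian,
    rhs_scaled,
    routh_hurwitz_minors,
    vl_system_matrix,
)
from seats.fixtures import generate_parameter_fixtures, random_simplex_states
from seats.stability import _symmetrized


class TestJacobian:
    def test_dfe_first_row(self, p_super):
        J = jacobian(animosity_free_equilibrium(), p_super)
        np.testing.assert_allclose(J[0], [-p_super.mu, 0.0, -p_super.beta, p_super.alpha])

    def test_column_sums_reflect_turnover(self, p_super):
        # summing the scaled RHS gives mu*(1 - s-e-v-z), so 1^T J = -mu * 1^T
        J = jacobian((0.4, 0.3, 0.2, 0.1), p_super)
        np.testing.assert_allclose(J.sum(axis=0), -p_super.mu * np.ones(4), atol=1e-14)

    def test_matches_finite_differences(self, p_super):
        state = np.array([0.5, 0.2, 0.2, 0.1])
        J = jacobian(state, p_super)
        h = 1e-6
        for j in range(4):
            dp = state.copy(); dp[j] += h
            dm = state.copy(); dm[j] -= h
            col = (rhs_scaled(dp, p_super) - rhs_scaled(dm, p_super)) / (2 * h)
            np.testing.assert_allclose(J[:, j], col, atol=1e-6)


class TestCharacteristicPolynomial:
    def test_negative_identity(self):
        np.testing.assert_allclose(
            characteristic_polynomial(-np.eye(4)), [1, 4, 6, 4, 1], atol=1e-12
        )

    def test_diagonal_matrix(self):
        got = characteristic_polynomial(np.diag([-1.0, -2.0, -3.0, -4.0]))
        np.testing.assert_allclose(got, [1, 10, 35, 50, 24], atol=1e-10)

    def test_roots_match_eigendecomposition(self, p_super):
        J = jacobian(endemic_equilibrium(p_super), p_super)
        roots = np.sort_complex(np.roots(characteristic_polynomial(J)))
        eig = np.sort_complex(np.linalg.eigvals(J))
        np.testing.assert_allclose(roots, eig, atol=1e-8)


class TestRouthHurwitz:
    def test_stable_quadratic(self):
        minors = routh_hurwitz_minors([1, 3, 2])  # roots -1, -2
        np.testing.assert_allclose(minors, [3, 6])

    def test_unstable_quadratic(self):
        minors = routh_hurwitz_minors([1, 1, -2])  # roots 1, -2
        assert minors[-1] < 0

    def test_non_monic_rejected(self):
        with pytest.raises(ValueError):
            routh_hurwitz_minors([2, 1, 1])

    def test_equivalence_with_root_signs(self, rng):
        # quartics built from known roots: all minors positive <=> stable
        for _ in range(500):
            if rng.random() < 0.5:
                re = -rng.uniform(0.05, 3.0, size=2)
            else:
                re = rng.uniform(-3.0, 3.0, size=2)
            im = rng.uniform(0.0, 3.0, size=2)
            roots = np.array([
                re[0] + 1j * im[0], re[0] - 1j * im[0],
                re[1] + 1j * im[1], re[1] - 1j * im[1],
            ])
            coeffs = np.poly(roots).real
            stable = bool(np.max(roots.real) < -1e-9)
            if abs(np.max(roots.real)) < 1e-9:
                continue
            assert bool(np.all(routh_hurwitz_minors(coeffs) > 0)) == stable


class TestLocalClassification:
    def test_dfe_unstable_when_supercritical(self, p_super):
        report = classify_local_stability(animosity_free_equilibrium(), p_super)
        assert report.verdict == "unstable"
        # dominant root of lambda^2 + 0.09 lambda - 0.0182
        assert report.max_real_part == pytest.approx(0.097215, abs=1e-5)

    def test_endemic_stable_when_supercritical(self, p_super):
        report = classify_local_stability(endemic_equilibrium(p_super), p_super)
        assert report.verdict == "stable"
        assert np.all(report.routh_hurwitz_minors > 0)

    def test_dfe_verdict_tracks_threshold(self):
        for p in generate_parameter_fixtures(200, "mixed", seed=5):
            r0 = basic_reproduction_number(p)
            if abs(r0 - 1.0) < 1e-6:
                continue
            verdict = classify_local_stability(animosity_free_equilibrium(), p).verdict
            assert verdict == ("stable" if r0 < 1 else "unstable")


class TestDfeLyapunov:
    def test_zero_at_no_infection(self, p_super):
        assert dfe_lyapunov_derivative(0.0, p_super) == 0.0

    def test_zero_at_threshold(self, p_sub):
        beta_crit = p_sub.beta / basic_reproduction_number(p_sub)
        p = p_sub.with_(beta=beta_crit)
        assert dfe_lyapunov_derivative(0.3, p) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value(self, p_super):
        assert dfe_lyapunov_derivative(0.1, p_super) == pytest.approx(0.505556, abs=1e-4)

    def test_matches_chain_rule_at_full_susceptibility(self, p_super, p_sub):
        # the exact orbital derivative is beta*(R0*s - 1)*v; at s = 1 it
        # coincides with the reported bound beta*(R0 - 1)*v
        h = 1e-7
        for p in (p_super, p_sub):
            for e, v in [(0.0, 0.1), (0.2, 0.05), (0.01, 0.4)]:
                state = np.array([1.0, e, v, 0.0])
                deriv = rhs_scaled(state, p)
                num = (
                    dfe_lyapunov_value(state + h * deriv, p)
                    - dfe_lyapunov_value(state - h * deriv, p)
                ) / (2 * h)
                assert num == pytest.approx(dfe_lyapunov_derivative(v, p), abs=1e-8)

    def test_bounds_chain_rule_on_simplex(self, p_sub):
        # on the simplex s <= 1, so the reported value is an upper bound
        for state in random_simplex_states(50, seed=9):
            c = seats.dfe_lyapunov_coefficients(p_sub)
            exact = c.m_coeff * rhs_scaled(state, p_sub)[1] + c.n_coeff * rhs_scaled(state, p_sub)[2]
            assert exact <= dfe_lyapunov_derivative(state[2], p_sub) + 1e-12


class TestDiagonalStability:
    def test_vl_stable_negative_identity(self):
        assert is_vl_stable_2x2(-np.eye(2)) is True

    def test_vl_unstable_mixed_signs(self):
        assert is_vl_stable_2x2(np.array([[-1.0, 0.0], [0.0, 1.0]])) is False

    def test_vl_2x2_agrees_with_grid_search(self, rng):
        # brute-force witness search over a positive grid as oracle
        grid = np.logspace(-3, 3, 25)
        for _ in range(60):
            A = rng.normal(scale=1.5, size=(2, 2))
            claimed = is_vl_stable_2x2(A)
            found = any(
                np.linalg.eigvalsh(np.diag([1.0, v2]) @ A + A.T @ np.diag([1.0, v2]))[-1] < 0
                for v2 in grid
            )
            if claimed:
                ok, W = is_vl_stable_2x2(A, return_witness=True)
                assert W is not None
                assert np.linalg.eigvalsh(_symmetrized(A, W))[-1] < 0
            else:
                assert not found

    def test_identity_is_diagonally_stable(self):
        ok, W = is_diagonally_stable(np.eye(3))
        assert ok and np.all(W > 0)

    def test_nonpositive_diagonal_fails(self):
        ok, W = is_diagonally_stable(np.array([[1.0, 0.0], [0.0, -0.5]]))
        assert not ok and W is None

    def test_diagonally_dominant_matrices_certify(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 5))
            A = rng.normal(scale=0.3, size=(n, n))
            A[np.arange(n), np.arange(n)] = np.abs(A).sum(axis=1) + rng.uniform(0.5, 2.0, n)
            ok, W = is_diagonally_stable(A)
            assert ok
            assert np.linalg.eigvalsh(_symmetrized(A, W))[0] > 0


class TestEndemicGlobalCertificate:
    def test_supercritical_preset_certifies(self, p_super):
        ws = certify_endemic_global_stability(p_super)
        assert ws.certified and ws.m_stable and ws.c_stable
        assert ws.lambda_max < 0
        np.testing.assert_allclose(
            np.linalg.eigvalsh(_symmetrized(ws.a_matrix, ws.diag_weights))[-1],
            ws.lambda_max,
        )

    def test_reduced_block_entry_sign(self, p_super):
        # the (3,3) entry of -A~ is mu + delta, positive for any parameters
        ws = certify_endemic_global_stability(p_super)
        assert ws.m_matrix[2, 2] == pytest.approx(p_super.mu + p_super.delta)

    def test_subcritical_rejected(self):
        p = ModelParameters(beta=0.01, gamma=0.035, delta=0.01, alpha=0.03, mu=0.02)
        with pytest.raises(ParameterError):
            certify_endemic_global_stability(p)

    def test_random_supercritical_sweep(self):
        for p in generate_parameter_fixtures(40, "super", seed=21):
            ws = certify_endemic_global_stability(p)
            assert ws.certified, f"certification failed at {p}"
            assert np.linalg.eigvalsh(_symmetrized(ws.a_matrix, ws.diag_weights))[-1] < 0

    def test_system_matrix_shape_and_blocks(self, p_super):
        A = vl_system_matrix(p_super)
        ws = certify_endemic_global_stability(p_super)
        np.testing.assert_allclose(ws.m_matrix, -A[:3, :3])
        np.testing.assert_allclose(ws.c_matrix, -np.linalg.inv(A)[:3, :3])
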