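"""Local and global stability certification for the SEATS equilibria.

Local stability is decided from the Jacobian of the scaled system:
eigenvalues directly, plus the Routh-Hurwitz leading-minor determinants of
the (monic) characteristic polynomial as an independent algebraic route.

Global stability is certified numerically.  For the animosity-free
equilibrium the linear Lyapunov function ``l(e, v) = m*e + n*v`` with
``m = beta*gamma/((mu+gamma)(mu+delta))`` and ``n = beta/(mu+delta)`` has
exact orbital derivative ``beta*(R0*s - 1)*v``, bounded above on the
simplex by ``beta*(R0 - 1)*v``, which is negative when R0 < 1.  For the
interior equilibrium the quadratic form ``L = sum v_i (x_i - x_i*)^2``
works whenever the system matrix ``A`` (the Jacobian at the equilibrium)
is Volterra-Lyapunov stable, i.e. some positive diagonal ``V`` makes
``V A + A^T V`` negative definite.  The witness ``V`` is constructed by
the classical recursive reduction (leading principal block + Schur
complement in the last weight) with a derivative-free polish as fallback,
and every certificate is re-checked by a direct eigenvalue computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, SingularParametersError
from .model import (
    ScaledState,
    _as_state_array,
    basic_reproduction_number,
    endemic_equilibrium,
)
from .params import ModelParameters

#: |max real part| below this is reported as marginal
MARGINAL_TOL = 1e-9


# ---------------------------------------------------------------------------
# local stability
# ---------------------------------------------------------------------------

def jacobian(state: Sequence[float], params: ModelParameters) -> np.ndarray:
    """Jacobian of the scaled vector field at ``state`` (4x4)."""
    s, _e, v, _z = _as_state_array(state)
    p = params
    return np.array(
        [
            [-p.mu - p.beta * v, 0.0, -p.beta * s, p.alpha],
            [p.beta * v, -(p.mu + p.gamma), p.beta * s, 0.0],
            [0.0, p.gamma, -(p.mu + p.delta), 0.0],
            [0.0, 0.0, p.delta, -(p.mu + p.alpha)],
        ]
    )


def characteristic_polynomial(matrix: np.ndarray) -> np.ndarray:
    """Monic characteristic polynomial coefficients of a square matrix.

    Returns ``[1, a1, ..., an]`` for ``lambda^n + a1 lambda^(n-1) + ... + an``,
    computed by the Faddeev-LeVerrier trace recursion (no eigenvalue call,
    so eigenvalue-based checks stay independent).
    """
    A = np.asarray(matrix, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("matrix must be square")
    coeffs = np.empty(n + 1)
    coeffs[0] = 1.0
    M = np.zeros_like(A)
    c = 1.0
    for k in range(1, n + 1):
        M = A @ M + c * np.eye(n)
        c = -np.trace(A @ M) / k
        coeffs[k] = c
    return coeffs


def routh_hurwitz_minors(coeffs: Sequence[float]) -> np.ndarray:
    """Leading-minor determinants of the Hurwitz matrix of a monic polynomial.

    ``coeffs`` is ``[a0, a1, ..., an]`` with ``a0 == 1``.  All minors
    positive is equivalent (for monic polynomials) to every root having
    negative real part.
    """
    a = np.asarray(coeffs, dtype=float)
    if a[0] != 1.0:
        raise ValueError("polynomial must be monic (a0 == 1)")
    n = a.size - 1

    def coef(k: int) -> float:
        return a[k] if 0 <= k <= n else 0.0

    minors = np.empty(n)
    for j in range(1, n + 1):
        H = np.array([[coef(2 * (i + 1) - (m + 1)) for m in range(j)] for i in range(j)])
        minors[j - 1] = np.linalg.det(H)
    return minors


@dataclass
class StabilityReport:
    """Eigenvalues, Hurwitz minors and the resulting verdict at one point."""

    equilibrium: ScaledState
    eigenvalues: np.ndarray
    max_real_part: float
    routh_hurwitz_minors: np.ndarray
    verdict: str  # "stable" | "unstable" | "marginal"


def classify_local_stability(
    equilibrium: Sequence[float],
    params: ModelParameters,
    tol: float = MARGINAL_TOL,
) -> StabilityReport:
    """Classify an equilibrium from the eigenvalues of its Jacobian."""
    eq = ScaledState(*_as_state_array(equilibrium))
    J = jacobian(eq, params)
    eig = np.linalg.eigvals(J)
    max_real = float(np.max(eig.real))
    minors = routh_hurwitz_minors(characteristic_polynomial(J))
    if abs(max_real) < tol:
        verdict = "marginal"
    elif max_real < 0.0:
        verdict = "stable"
    else:
        verdict = "unstable"
    return StabilityReport(
        equilibrium=eq,
        eigenvalues=eig,
        max_real_part=max_real,
        routh_hurwitz_minors=minors,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# linear Lyapunov function for the animosity-free equilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DfeLyapunovCoefficients:
    """Weights of the linear Lyapunov function ``l(e, v) = m*e + n*v``."""

    m_coeff: float
    n_coeff: float


def dfe_lyapunov_coefficients(params: ModelParameters) -> DfeLyapunovCoefficients:
    if params.beta <= 0:
        raise ParameterError("the linear Lyapunov weights require beta > 0")
    m = basic_reproduction_number(params)
    n = params.beta / (params.mu + params.delta)
    return DfeLyapunovCoefficients(m_coeff=m, n_coeff=n)


def dfe_lyapunov_value(state: Sequence[float], params: ModelParameters) -> float:
    """``l(e, v) = m*e + n*v`` evaluated at a state."""
    _s, e, v, _z = _as_state_array(state)
    c = dfe_lyapunov_coefficients(params)
    return c.m_coeff * e + c.n_coeff * v


def dfe_lyapunov_derivative(v_component: float, params: ModelParameters) -> float:
    """Orbital derivative bound ``beta*(R0 - 1)*v`` of ``l`` at the boundary.

    The exact chain-rule derivative along the flow is
    ``beta*(R0*s - 1)*v``; this equals the returned value at ``s = 1`` and
    is bounded above by it anywhere on the simplex, so the sign of
    ``R0 - 1`` decides global stability of the animosity-free point.
    """
    r0 = basic_reproduction_number(params)
    return params.beta * (r0 - 1.0) * v_component


# ---------------------------------------------------------------------------
# diagonal / Volterra-Lyapunov stability
# ---------------------------------------------------------------------------

def _symmetrized(B: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """``V B + B^T V`` for ``V = diag(weights)``."""
    return weights[:, None] * B + B.T * weights[None, :]


def _min_eig(M: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(M)[0])


def _witness_2x2(B: np.ndarray) -> np.ndarray | None:
    """Positive diagonal ``(1, v2)`` with ``VB + B^T V`` positive definite."""
    b11, b12 = B[0, 0], B[0, 1]
    b21, b22 = B[1, 0], B[1, 1]
    if b11 <= 0 or b22 <= 0 or b11 * b22 - b12 * b21 <= 0:
        return None
    # need (b12 + v2*b21)^2 < 4*v2*b11*b22  (v1 = 1)
    qa = b21 * b21
    qb = 2.0 * b12 * b21 - 4.0 * b11 * b22
    qc = b12 * b12
    if qa == 0.0:
        v2 = 1.0 if qc == 0.0 else 2.0 * qc / (-qb)
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc <= 0.0:
            return None
        lo = (-qb - np.sqrt(disc)) / (2.0 * qa)
        hi = (-qb + np.sqrt(disc)) / (2.0 * qa)
        if hi <= 0.0:
            return None
        lo = max(lo, 0.0)
        v2 = 0.5 * (lo + hi)
    V = np.array([1.0, v2])
    return V if _min_eig(_symmetrized(B, V)) > 0.0 else None


def _witness_polish(B: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray | None:
    """Derivative-free search for a witness, used when the recursion stalls."""
    from scipy.optimize import minimize

    n = B.shape[0]
    starts = [np.zeros(n)]
    if x0 is not None:
        starts.insert(0, np.log(np.maximum(x0, 1e-12)))
    rng = np.random.default_rng(12345)
    starts += [rng.normal(scale=2.0, size=n) for _ in range(4)]
    for start in starts:
        res = minimize(
            lambda logv: -_min_eig(_symmetrized(B, np.exp(logv))) / np.exp(logv).max(),
            start,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
        )
        V = np.exp(res.x)
        V /= V.max()
        if _min_eig(_symmetrized(B, V)) > 0.0:
            return V
    return None


def find_diagonal_witness(matrix: np.ndarray) -> np.ndarray | None:
    """Positive diagonal ``V`` with ``V B + B^T V`` positive definite, or None.

    Recursive construction: find a witness for the leading principal block,
    then pick the last weight from the (closed-form quadratic) positivity
    condition on the Schur complement.  Falls back to a Nelder-Mead search
    before giving up.  The returned witness is always verified.
    """
    B = np.asarray(matrix, dtype=float)
    n = B.shape[0]
    if n == 1:
        return np.array([1.0]) if B[0, 0] > 0 else None
    if np.any(np.diag(B) <= 0.0):
        return None  # positive diagonal is necessary
    if n == 2:
        W = _witness_2x2(B)
        return W if W is not None else _witness_polish(B)

    Vt = find_diagonal_witness(B[:-1, :-1])
    if Vt is not None and _min_eig(_symmetrized(B[:-1, :-1], Vt)) > 0.0:
        # Positivity of the Schur complement in the last weight is a concave
        # quadratic; rather than the bare root midpoint, maximise the overall
        # definiteness margin over v_n (robust when the root interval is thin).
        def margin(log_vn: float) -> float:
            V = np.append(Vt, np.exp(log_vn))
            return _min_eig(_symmetrized(B, V)) / V.max()

        grid = np.linspace(-8.0, 8.0, 65)
        best = max(grid, key=margin)
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda x: -margin(x), bounds=(best - 1.0, best + 1.0), method="bounded"
        )
        cand = res.x if margin(res.x) > margin(best) else best
        V = np.append(Vt, np.exp(cand))
        if _min_eig(_symmetrized(B, V)) > 0.0:
            return V
    return _witness_polish(B, np.append(Vt, 1.0) if Vt is not None else None)


def is_diagonally_stable(matrix: np.ndarray) -> tuple[bool, np.ndarray | None]:
    """Does a positive diagonal ``V`` make ``V B + B^T V`` positive definite?

    Returns ``(flag, witness)``; the witness satisfies the definiteness
    check to machine precision when the flag is true.
    """
    W = find_diagonal_witness(matrix)
    return (W is not None), W


def is_vl_stable_2x2(matrix: np.ndarray, return_witness: bool = False):
    """Volterra-Lyapunov stability of a 2x2 matrix.

    True iff ``a11 < 0``, ``a22 < 0`` and ``det(A) > 0`` (negative-definite
    convention: some positive diagonal ``V`` gives ``VA + A^T V < 0``).
    """
    A = np.asarray(matrix, dtype=float)
    if A.shape != (2, 2):
        raise ValueError("expected a 2x2 matrix")
    ok = bool(A[0, 0] < 0.0 and A[1, 1] < 0.0 and np.linalg.det(A) > 0.0)
    if not return_witness:
        return ok
    return ok, (find_diagonal_witness(-A) if ok else None)


# ---------------------------------------------------------------------------
# global stability certificate for the interior equilibrium
# ---------------------------------------------------------------------------

def vl_system_matrix(params: ModelParameters) -> np.ndarray:
    """Quadratic-form system matrix of the interior Lyapunov argument.

    Both bilinear cross terms of the contact nonlinearity carry the weight
    ``beta*s*`` and the matrix is evaluated at the equilibrium (v = v*).
    This matrix differs from the Jacobian only in the sign of the (2, 3)
    entry; the Jacobian itself has the principal minor on the (e, v) block
    equal to ``(mu+gamma)(mu+delta)(1 - R0*s*) = 0`` exactly, so it can
    never be strictly diagonally stable — the certificate is about this
    quadratic-form matrix, not the linearisation.
    """
    eq = endemic_equilibrium(params)
    if eq is None:
        raise ParameterError("interior equilibrium does not exist (R0 < 1)")
    p = params
    bs = p.beta * eq.s
    return np.array(
        [
            [-(p.mu + p.beta * eq.v), 0.0, -bs, p.alpha],
            [p.beta * eq.v, -(p.mu + p.gamma), -bs, 0.0],
            [0.0, p.gamma, -(p.mu + p.delta), 0.0],
            [0.0, 0.0, p.delta, -(p.mu + p.alpha)],
        ]
    )


@dataclass
class VLStabilityWorkspace:
    """Artifacts of the Volterra-Lyapunov certificate at the interior point.

    ``a_matrix`` is the quadratic-form system matrix (the Jacobian at the
    equilibrium); ``m_matrix`` and ``c_matrix`` are the reduced 3x3 blocks
    ``-A~`` and ``-(A^-1)~`` whose diagonal stability drives the recursive
    construction; ``diag_weights`` is the final witness when found.
    """

    a_matrix: np.ndarray
    m_matrix: np.ndarray
    c_matrix: np.ndarray
    diag_weights: np.ndarray | None
    certified: bool
    m_stable: bool = False
    c_stable: bool = False
    lambda_max: float = field(default=float("nan"))


def certify_endemic_global_stability(params: ModelParameters) -> VLStabilityWorkspace:
    """Numerically certify Volterra-Lyapunov stability at the interior point.

    Requires R0 > 1.  Builds the system matrix ``A`` at the equilibrium,
    checks the two reduced diagonal-stability conditions (on ``M = -A~``
    and ``C = -(A^-1)~``), assembles a full positive diagonal witness
    ``V``, and sets ``certified`` only if ``V A + A^T V`` is negative
    definite by a direct eigenvalue check.
    """
    r0 = basic_reproduction_number(params)
    if r0 <= 1.0:
        raise ParameterError(f"interior equilibrium requires R0 > 1 (got {r0:g})")
    A = vl_system_matrix(params)
    if params.mu + params.alpha <= 0.0:
        raise ParameterError("mu + alpha must be positive")
    M = -A[:3, :3]
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise SingularParametersError(f"system matrix is singular: {exc}") from exc
    C = -Ainv[:3, :3]

    m_stable, _ = is_diagonally_stable(M)
    c_stable, _ = is_diagonally_stable(C)
    W = find_diagonal_witness(-A)
    if W is not None:
        lam = float(np.linalg.eigvalsh(_symmetrized(A, W))[-1])
        certified = m_stable and c_stable and lam < 0.0
    else:
        lam = float("nan")
        certified = False
    return VLStabilityWorkspace(
        a_matrix=A,
        m_matrix=M,
        c_matrix=C,
        diag_weights=W,
        certified=certified,
        m_stable=m_stable,
        c_stable=c_stable,
        lambda_max=lam,
    )
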