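"""Deterministic SEATS dynamics: state spaces, vector fields, equilibria.

Two equivalent descriptions are provided.  The *count* system tracks raw
head counts (S, E, A, T) with recruitment ``Lambda = mu*N`` and a
density-dependent contact term ``beta*S*A``.  The *scaled* system tracks
proportions (s, e, v, z) on the unit simplex:

    ds/dt = mu + alpha*z - beta*s*v - mu*s
    de/dt = beta*s*v - (mu + gamma)*e
    dv/dt = gamma*e - (mu + delta)*v
    dz/dt = delta*v - (mu + alpha)*z

The threshold quantity is the basic reproduction number

    R0 = beta*gamma / ((mu + gamma) * (mu + delta)),

the spectral radius of the next-generation matrix F V^-1 of the scaled
system.  Below 1 only the animosity-free equilibrium (1, 0, 0, 0) exists;
at and above 1 an interior (animosity-dominance) equilibrium appears with
s* = 1/R0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidStateError, ParameterError, SingularParametersError
from .params import ModelParameters

#: tolerance for "is this state on the simplex" input validation
SIMPLEX_TOL = 1e-8


class ScaledState(NamedTuple):
    """Proportions of the four compartments; must sum to 1."""

    s: float
    e: float
    v: float
    z: float


class PopulationState(NamedTuple):
    """Raw head counts of the four compartments; must sum to ``n_total``."""

    s_count: float
    e_count: float
    a_count: float
    t_count: float


@dataclass
class Trajectory:
    """Time-indexed solution of a deterministic or stochastic run.

    ``states`` is an ``(n_times, 4)`` array; ``kind`` is ``"scaled"``
    (columns s, e, v, z) or ``"counts"`` (columns S, E, A, T).
    """

    times: np.ndarray
    states: np.ndarray
    kind: str = "scaled"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise InvalidStateError(
                f"states shape {self.states.shape} does not match {self.times.size} times"
            )

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        """Return the trajectory as a pandas DataFrame."""
        import pandas as pd

        columns = ["s", "e", "v", "z"] if self.kind == "scaled" else ["S", "E", "A", "T"]
        frame = pd.DataFrame(self.states, columns=columns)
        frame.insert(0, "time", self.times)
        return frame


def _as_state_array(state: Sequence[float]) -> np.ndarray:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (4,):
        raise InvalidStateError(f"state must have 4 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidStateError(f"state has non-finite components: {arr!r}")
    return arr


def validate_scaled_state(state: Sequence[float], tol: float = SIMPLEX_TOL) -> np.ndarray:
    """Check that ``state`` lies on the unit simplex within ``tol``."""
    arr = _as_state_array(state)
    if abs(arr.sum() - 1.0) > tol or np.any(arr < -tol):
        raise InvalidStateError(
            f"state {arr!r} is off the unit simplex (sum {arr.sum():.3e})"
        )
    return arr


def rhs_scaled(state: Sequence[float], params: ModelParameters) -> np.ndarray:
    """Time derivatives (per month) of the scaled system at ``state``.

    On the simplex the four components sum to zero (constant population);
    off the simplex the sum is ``mu*(1 - s - e - v - z)``.
    """
    s, e, v, z = _as_state_array(state)
    p = params
    return np.array(
        [
            p.mu + p.alpha * z - p.beta * s * v - p.mu * s,
            p.beta * s * v - (p.mu + p.gamma) * e,
            p.gamma * e - (p.mu + p.delta) * v,
            p.delta * v - (p.mu + p.alpha) * z,
        ]
    )


def rhs_unscaled(state: Sequence[float], params: ModelParameters) -> np.ndarray:
    """Time derivatives (students per month) of the count system.

    The contact term is ``beta*S*A`` on raw counts; with ``n_total = 1``
    this coincides with :func:`rhs_scaled` on the same numbers.  The four
    components always sum to ``mu*(N - S - E - A - T)``, hence to zero on
    any state with the correct total.
    """
    S, E, A, T = _as_state_array(state)
    p = params
    return np.array(
        [
            p.lambda_recruit + p.alpha * T - p.beta * S * A - p.mu * S,
            p.beta * S * A - (p.mu + p.gamma) * E,
            p.gamma * E - (p.mu + p.delta) * A,
            p.delta * A - (p.mu + p.alpha) * T,
        ]
    )


def basic_reproduction_number(params: ModelParameters) -> float:
    """``R0 = beta*gamma / ((mu+gamma)*(mu+delta))`` (dimensionless)."""
    denom = (params.mu + params.gamma) * (params.mu + params.delta)
    if denom <= 0.0:
        raise ParameterError("mu+gamma and mu+delta must both be positive for R0")
    return params.beta * params.gamma / denom


def animosity_free_equilibrium() -> ScaledState:
    """The boundary equilibrium with the whole population susceptible."""
    return ScaledState(1.0, 0.0, 0.0, 0.0)


def endemic_equilibrium(params: ModelParameters) -> ScaledState | None:
    """Interior (animosity-dominance) equilibrium, or ``None`` if R0 < 1.

    Closed form: ``s* = 1/R0``, ``v*`` from the quotient below,
    ``e* = (mu+delta)*v*/gamma``, ``z* = delta*v*/(mu+alpha)``.  At
    ``R0 == 1`` the interior point coincides with the animosity-free one
    (continuity limit).
    """
    r0 = basic_reproduction_number(params)
    if r0 < 1.0:
        return None
    if r0 == 1.0:
        return animosity_free_equilibrium()
    p = params
    denom = p.alpha * p.delta * p.gamma - (p.mu + p.alpha) * (p.mu + p.delta) * (p.mu + p.gamma)
    if denom == 0.0:
        raise SingularParametersError(
            "alpha*delta*gamma == (mu+alpha)(mu+delta)(mu+gamma): interior "
            "equilibrium is degenerate at these parameters"
        )
    v_star = (1.0 / r0 - 1.0) * p.gamma * p.mu * (p.mu + p.alpha) / denom
    e_star = (p.mu + p.delta) * v_star / p.gamma
    z_star = p.delta * v_star / (p.mu + p.alpha)
    return ScaledState(1.0 / r0, e_star, v_star, z_star)


def scale(state: Sequence[float], params: ModelParameters) -> ScaledState:
    """Convert raw counts to proportions (divide by ``n_total``)."""
    arr = _as_state_array(state)
    return ScaledState(*(arr / params.n_total))


def unscale(state: Sequence[float], params: ModelParameters) -> PopulationState:
    """Convert proportions to raw counts (multiply by ``n_total``)."""
    arr = _as_state_array(state)
    return PopulationState(*(arr * params.n_total))


def simulate(
    params: ModelParameters,
    init: Sequence[float],
    t_final: float,
    *,
    n_points: int = 601,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the scaled system with an adaptive Runge-Kutta (4,5) pair.

    ``init`` must lie on the simplex within :data:`SIMPLEX_TOL`.  Output is
    evaluated on ``t_eval`` (default: ``n_points`` uniform samples on
    ``[0, t_final]``).  The simplex is *not* re-projected; conservation is
    left to the solver and checked by the test suite.
    """
    y0 = validate_scaled_state(init)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_final, n_points)
    sol = solve_ivp(
        lambda _t, y: rhs_scaled(y, params),
        (0.0, float(t_final)),
        y0,
        method=method,
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_time=last)
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        kind="scaled",
        meta={"params": params, "rtol": rtol, "atol": atol, "method": method},
    )


def simulate_counts(
    params: ModelParameters,
    init: Sequence[float],
    t_final: float,
    *,
    n_points: int = 601,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the count system (columns S, E, A, T)."""
    y0 = _as_state_array(init)
    if abs(y0.sum() - params.n_total) > SIMPLEX_TOL * max(1.0, params.n_total):
        raise InvalidStateError(
            f"counts sum to {y0.sum():g}, expected n_total = {params.n_total:g}"
        )
    if t_eval is None:
        t_eval = np.linspace(0.0, t_final, n_points)
    sol = solve_ivp(
        lambda _t, y: rhs_unscaled(y, params),
        (0.0, float(t_final)),
        y0,
        method=method,
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_time=last)
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        kind="counts",
        meta={"params": params, "rtol": rtol, "atol": atol, "method": method},
    )


@dataclass(frozen=True)
class AnalysisSummary:
    """R0 plus both equilibria for one parameter set."""

    r0: float
    dfe: ScaledState
    endemic: ScaledState | None
    endemic_exists: bool


def analyze(params: ModelParameters) -> AnalysisSummary:
    """Compute R0 and the equilibria in one call."""
    r0 = basic_reproduction_number(params)
    endemic = endemic_equilibrium(params)
    return AnalysisSummary(
        r0=r0,
        dfe=animosity_free_equilibrium(),
        endemic=endemic,
        endemic_exists=endemic is not None,
    )
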