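"""Continuous-time Markov chain (CTMC) variant of the SEATS model.

The chain tracks the integer counts (S, E, A); the treated count is the
remainder ``T = N - S - E - A``.  Six state-changing events occur at the
following propensities (per month):

    (S+1)           mu*N + alpha*T      turnover influx + return of treated
    (S-1, E+1)      beta*S*A            contact / exposure
    (S-1)           mu*S                turnover exit from S
    (E-1, A+1)      gamma*E             progression to animosity
    (E-1)           mu*E                turnover exit from E
    (A-1)           (mu + delta)*A      turnover exit or treatment of A

``theta`` is the total rate.  Exact event-driven (Gillespie) simulation
draws exponential waiting times with rate ``theta`` and picks the event
proportionally to its propensity.  The influx event is suppressed when
``S + E + A == N`` so the implicit treated count never goes negative.

The outbreak assessment follows the threshold rule: extinction is certain
when the expected number of animosity-infected students ``n`` is at most
1; otherwise the extinction probability is ``tau = N/(s*R0)`` (clamped to
[0, 1]) and the outbreak probability is ``1 - tau``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidStateError, ParameterError
from .model import PopulationState, Trajectory, basic_reproduction_number
from .params import ModelParameters


@dataclass(frozen=True)
class TransitionEvent:
    """One CTMC event: integer change to (S, E, A) and its propensity."""

    delta: tuple[int, int, int]
    rate: float
    label: str


_DELTAS = (
    (1, 0, 0),
    (-1, 1, 0),
    (-1, 0, 0),
    (0, -1, 1),
    (0, -1, 0),
    (0, 0, -1),
)
_LABELS = (
    "influx_to_S",
    "exposure",
    "exit_from_S",
    "progression",
    "exit_from_E",
    "removal_from_A",
)


def _check_counts(state: Sequence[float], n_total: float) -> tuple[int, int, int, int]:
    S, E, A, T = (float(x) for x in state)
    if min(S, E, A, T) < 0:
        raise InvalidStateError(f"negative count in state {tuple(state)!r}")
    if abs(S + E + A + T - n_total) > 1e-9 * max(1.0, n_total):
        raise InvalidStateError(
            f"counts sum to {S + E + A + T:g}, expected n_total = {n_total:g}"
        )
    return int(round(S)), int(round(E)), int(round(A)), int(round(T))


def _rates(S: float, E: float, A: float, N: float, p: ModelParameters) -> tuple:
    T = N - S - E - A
    influx = p.mu * N + p.alpha * T if S + E + A < N else 0.0
    return (
        influx,
        p.beta * S * A,
        p.mu * S,
        p.gamma * E,
        p.mu * E,
        (p.mu + p.delta) * A,
    )


def transition_rates(
    state: Sequence[float], params: ModelParameters
) -> list[TransitionEvent]:
    """Evaluate the six event propensities at a count state (S, E, A, T)."""
    S, E, A, _T = _check_counts(state, params.n_total)
    rates = _rates(S, E, A, params.n_total, params)
    return [
        TransitionEvent(delta=d, rate=r, label=lbl)
        for d, r, lbl in zip(_DELTAS, rates, _LABELS)
    ]


def total_rate(state: Sequence[float], params: ModelParameters) -> float:
    """``theta``: the sum of the six event propensities."""
    return sum(ev.rate for ev in transition_rates(state, params))


def gillespie_simulate(
    params: ModelParameters,
    init: Sequence[float],
    t_max: float,
    rng_seed: int,
    max_events: int | None = None,
) -> Trajectory:
    """Exact stochastic simulation; returns the full jump trajectory.

    The trajectory ends early (flag ``meta["absorbed"]``) if the total rate
    reaches zero.  Identical seeds give identical trajectories.
    """
    S, E, A, _T = _check_counts(init, params.n_total)
    N = params.n_total
    rng = random.Random(rng_seed)
    t = 0.0
    times = [0.0]
    states = [(S, E, A, N - S - E - A)]
    absorbed = False
    n_events = 0
    while t < t_max:
        rates = _rates(S, E, A, N, params)
        theta = sum(rates)
        if theta <= 0.0:
            absorbed = True
            break
        t += -np.log(rng.random()) / theta
        if t >= t_max:
            break
        u = rng.random() * theta
        acc = 0.0
        for k, r in enumerate(rates):
            acc += r
            if u < acc:
                dS, dE, dA = _DELTAS[k]
                S += dS
                E += dE
                A += dA
                break
        times.append(t)
        states.append((S, E, A, N - S - E - A))
        n_events += 1
        if max_events is not None and n_events >= max_events:
            break
    return Trajectory(
        times=np.array(times),
        states=np.array(states, dtype=float),
        kind="counts",
        meta={"params": params, "seed": rng_seed, "absorbed": absorbed},
    )


def gillespie_ensemble(
    params: ModelParameters,
    init: Sequence[float],
    t_grid: Sequence[float],
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Sample ``n_reps`` replicates at fixed checkpoint times.

    Returns an ``(n_reps, len(t_grid), 4)`` array of (S, E, A, T) counts.
    Memory-light alternative to storing full jump trajectories.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    S0, E0, A0, _T0 = _check_counts(init, params.n_total)
    N = params.n_total
    out = np.empty((n_reps, t_grid.size, 4))
    root = random.Random(seed)
    for rep in range(n_reps):
        rng = random.Random(root.randrange(2**31))
        S, E, A = S0, E0, A0
        t = 0.0
        gi = 0
        while gi < t_grid.size:
            rates = _rates(S, E, A, N, params)
            theta = rates[0] + rates[1] + rates[2] + rates[3] + rates[4] + rates[5]
            if theta <= 0.0:
                t = np.inf
            else:
                t += -np.log(rng.random()) / theta
            while gi < t_grid.size and t >= t_grid[gi]:
                out[rep, gi] = (S, E, A, N - S - E - A)
                gi += 1
            if gi >= t_grid.size:
                break
            u = rng.random() * theta
            acc = 0.0
            for k in range(6):
                acc += rates[k]
                if u < acc:
                    dS, dE, dA = _DELTAS[k]
                    S += dS
                    E += dE
                    A += dA
                    break
    return out


@dataclass(frozen=True)
class OutbreakAssessment:
    """Threshold-rule extinction/outbreak probabilities."""

    n_expected: float
    tau: float
    p_extinction: float
    p_outbreak: float


def outbreak_probability(
    n_expected: float,
    s_count: float,
    params: ModelParameters,
) -> OutbreakAssessment:
    """Extinction/outbreak probabilities from the threshold rule.

    ``n_expected`` is the expected number of animosity-infected students
    (an input; it shares its threshold role with R0 but is not computed
    here).  ``tau = N/(s*R0)``, clamped to [0, 1].
    """
    r0 = basic_reproduction_number(params)
    if n_expected <= 1.0:
        tau = 1.0
    else:
        if s_count <= 0.0:
            raise ParameterError("tau = N/(s*R0) is undefined for s_count == 0")
        if r0 <= 0.0:
            raise ParameterError("tau = N/(s*R0) is undefined for R0 == 0")
        tau = min(1.0, max(0.0, params.n_total / (s_count * r0)))
    p_ext = 1.0 if n_expected <= 1.0 else tau
    return OutbreakAssessment(
        n_expected=n_expected,
        tau=tau,
        p_extinction=p_ext,
        p_outbreak=1.0 - p_ext,
    )


def estimate_outbreak_probability_empirical(
    params: ModelParameters,
    init: Sequence[float],
    t_max: float,
    n_reps: int,
    seed: int,
    extinction_threshold: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo outbreak probability with a binomial standard error.

    A replicate counts as extinct if A(t) reaches ``extinction_threshold``
    before ``t_max``; the outbreak fraction is 1 minus the extinct
    fraction.  Returns ``(p_outbreak_hat, standard_error)``.
    """
    S0, E0, A0, _T0 = _check_counts(init, params.n_total)
    N = params.n_total
    root = random.Random(seed)
    extinct = 0
    for _rep in range(n_reps):
        rng = random.Random(root.randrange(2**31))
        S, E, A = S0, E0, A0
        t = 0.0
        while True:
            if A <= extinction_threshold:
                extinct += 1
                break
            rates = _rates(S, E, A, N, params)
            theta = sum(rates)
            if theta <= 0.0:
                break
            t += -np.log(rng.random()) / theta
            if t >= t_max:
                break
            u = rng.random() * theta
            acc = 0.0
            for k in range(6):
                acc += rates[k]
                if u < acc:
                    dS, dE, dA = _DELTAS[k]
                    S += dS
                    E += dE
                    A += dA
                    break
    p_ext = extinct / n_reps
    p_out = 1.0 - p_ext
    se = float(np.sqrt(max(p_out * p_ext, 0.0) / n_reps))
    return p_out, se
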