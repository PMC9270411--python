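"""Rate constants and cost weights of the SEATS contagion model.

The model tracks four groups of students — Susceptible, Exposed,
Animosity-infected and Treated — exchanging members at constant per-capita
rates.  All rates are per month; population turnover is balanced (equal
entry and exit rate ``mu``), so the total count ``N`` is constant and the
recruitment rate is the derived quantity ``Lambda = mu * N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

_RATE_FIELDS = ("beta", "gamma", "delta", "alpha", "mu")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the SEATS system.

    Parameters
    ----------
    beta : float
        Transmission (contact) rate between susceptible and
        animosity-infected students, per month.
    gamma : float
        Progression rate from exposed to animosity-infected, per month.
    delta : float
        Treatment (recovery-intervention) rate, per month.
    alpha : float
        Return rate from treated back to susceptible, per month.
    mu : float
        Balanced entry/exit (turnover) rate, per month.
    n_total : float
        Total number of students ``N``; constant over time.
    """

    beta: float
    gamma: float
    delta: float
    alpha: float
    mu: float
    n_total: float = 1.0

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not (value >= 0.0):  # also rejects NaN
                raise ParameterError(f"rate {name!r} must be >= 0, got {value!r}")
        if not (self.n_total > 0.0):
            raise ParameterError(f"n_total must be > 0, got {self.n_total!r}")

    @property
    def lambda_recruit(self) -> float:
        """Recruitment rate ``Lambda = mu * N`` (students per month)."""
        return self.mu * self.n_total

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class ControlWeights:
    """Cost weights of the optimal-control objective.

    ``w1`` prices the animosity-infected head count; ``b1`` and ``b2`` are
    quadratic effort weights for the prevention control ``u1`` and the
    treatment control ``u2``.
    """

    w1: float = 1.0
    b1: float = 100.0
    b2: float = 100.0

    def __post_init__(self) -> None:
        for name in ("w1", "b1", "b2"):
            if not (getattr(self, name) > 0.0):
                raise ParameterError(f"weight {name!r} must be > 0")
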