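"""Random parameter-set generation for property tests and sweeps.

Rates are drawn log-uniformly on [1e-3, 1] per month — spanning slow
turnover to monthly-scale transitions — and accepted or rejected by the
requested R0 regime.  The draw is fully determined by the seed.
"""

from __future__ import annotations

import numpy as np

from .model import basic_reproduction_number
from .params import ModelParameters

RATE_LOW = 1e-3
RATE_HIGH = 1.0


def generate_parameter_fixtures(
    n_sets: int,
    r0_regime: str = "mixed",
    seed: int = 0,
    n_total: float = 1.0,
    max_draws: int = 1_000_000,
) -> list[ModelParameters]:
    """Sample ``n_sets`` valid parameter sets in the given R0 regime.

    ``r0_regime`` is ``"sub"`` (R0 < 1), ``"super"`` (R0 > 1) or
    ``"mixed"`` (no rejection).  Identical seeds give identical sets.
    """
    if r0_regime not in ("sub", "super", "mixed"):
        raise ValueError(f"unknown r0_regime {r0_regime!r}")
    rng = np.random.default_rng(seed)
    out: list[ModelParameters] = []
    log_lo, log_hi = np.log(RATE_LOW), np.log(RATE_HIGH)
    draws = 0
    while len(out) < n_sets:
        draws += 1
        if draws > max_draws:
            raise RuntimeError("rejection sampling failed to fill the request")
        beta, gamma, delta, alpha, mu = np.exp(rng.uniform(log_lo, log_hi, size=5))
        params = ModelParameters(
            beta=beta, gamma=gamma, delta=delta, alpha=alpha, mu=mu, n_total=n_total
        )
        r0 = basic_reproduction_number(params)
        if r0_regime == "sub" and not r0 < 1.0:
            continue
        if r0_regime == "super" and not r0 > 1.0:
            continue
        out.append(params)
    return out


def random_simplex_states(n_states: int, seed: int = 0) -> np.ndarray:
    """Uniform (Dirichlet) samples on the 4-compartment simplex."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(4), size=n_states)
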