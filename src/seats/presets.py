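"""Bundled scenario presets for the reported figures and parameter sets.

``p1`` is the low-transmission set (beta = 0.05) and ``p2`` the
high-transmission set (beta = 0.5, gamma = 0.04); both share
gamma/alpha/mu/delta = 0.035/0.03/0.02/0.01 otherwise.  The shared scaled
initial condition is (0.74, 0.09, 0.07, 0.10) — the treated proportion is
fixed by conservation.  Control scenarios use beta = 0.04 on a population
of 100 with cost weights w1 = 1, b1 = b2 = 100 over 300 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ControlWeights, ModelParameters

#: scaled initial condition shared by the deterministic scenarios
DEFAULT_INIT = (0.74, 0.09, 0.07, 0.10)

P1 = ModelParameters(beta=0.05, gamma=0.035, delta=0.01, alpha=0.03, mu=0.02)
P2 = ModelParameters(beta=0.5, gamma=0.04, delta=0.01, alpha=0.03, mu=0.02)
CONTROL_PARAMS = ModelParameters(
    beta=0.04, gamma=0.035, delta=0.01, alpha=0.03, mu=0.02, n_total=100.0
)
CONTROL_INIT = (74.0, 9.0, 7.0, 10.0)


@dataclass
class ScenarioPreset:
    """One runnable scenario: parameters, initial state and run settings."""

    name: str
    params: ModelParameters
    init: tuple = DEFAULT_INIT
    t_final: float = 300.0
    kind: str = "deterministic"  # deterministic | stochastic | control | sweep
    control_mode: str = "both"
    weights: ControlWeights = field(default_factory=ControlWeights)
    seed: int = 0
    sweep_field: str | None = None
    sweep_values: tuple = ()
    n_reps: int = 100


PRESETS: dict[str, ScenarioPreset] = {}


def _register(preset: ScenarioPreset) -> ScenarioPreset:
    PRESETS[preset.name] = preset
    return preset


_register(ScenarioPreset(name="p1", params=P1))
_register(ScenarioPreset(name="p2", params=P2))
_register(ScenarioPreset(name="fig2", params=P1))
_register(ScenarioPreset(name="fig3", params=P2))
_register(
    ScenarioPreset(
        name="fig4",
        params=P1,
        kind="sweep",
        sweep_field="beta",
        sweep_values=(0.01, 0.03, 0.05, 0.07, 0.09),
    )
)
_register(
    ScenarioPreset(
        name="fig5",
        params=CONTROL_PARAMS.with_(n_total=1.0),
        kind="sweep",
        sweep_field="gamma",
        sweep_values=(0.015, 0.025, 0.035, 0.045, 0.055),
    )
)
_register(
    ScenarioPreset(
        name="fig6",
        params=CONTROL_PARAMS.with_(n_total=1.0),
        kind="sweep",
        sweep_field="delta",
        sweep_values=(0.005, 0.01, 0.02, 0.04, 0.08),
    )
)
for _name, _mode in (
    ("fig7", "both"),
    ("fig8", "treatment_only"),
    ("fig9", "prevention_only"),
):
    _register(
        ScenarioPreset(
            name=_name,
            params=CONTROL_PARAMS,
            init=CONTROL_INIT,
            t_final=300.0,
            kind="control",
            control_mode=_mode,
        )
    )


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
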