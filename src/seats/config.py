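"""YAML/JSON configuration round-trip for scenario presets."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .errors import InvalidStateError, ParameterError
from .params import ControlWeights, ModelParameters
from .presets import DEFAULT_INIT, ScenarioPreset

_PARAM_KEYS = ("beta", "gamma", "delta", "alpha", "mu")
_DEFAULTS = {
    "beta": 0.05,
    "gamma": 0.035,
    "delta": 0.01,
    "alpha": 0.03,
    "mu": 0.02,
    "n_total": 1.0,
    "init": list(DEFAULT_INIT),
    "t_final": 300.0,
    "kind": "deterministic",
    "control_mode": "both",
    "weights": {"w1": 1.0, "b1": 100.0, "b2": 100.0},
    "seed": 0,
    "n_reps": 100,
}


def preset_to_dict(preset: ScenarioPreset) -> dict:
    data = {
        "name": preset.name,
        "beta": preset.params.beta,
        "gamma": preset.params.gamma,
        "delta": preset.params.delta,
        "alpha": preset.params.alpha,
        "mu": preset.params.mu,
        "n_total": preset.params.n_total,
        "init": list(preset.init),
        "t_final": preset.t_final,
        "kind": preset.kind,
        "control_mode": preset.control_mode,
        "weights": asdict(preset.weights),
        "seed": preset.seed,
        "n_reps": preset.n_reps,
    }
    if preset.sweep_field is not None:
        data["sweep_field"] = preset.sweep_field
        data["sweep_values"] = list(preset.sweep_values)
    return data


def preset_from_dict(data: dict, name: str = "custom") -> ScenarioPreset:
    merged = {**_DEFAULTS, **data}
    for key in _PARAM_KEYS:
        if merged[key] < 0:
            raise ParameterError(f"rate {key!r} must be nonnegative, got {merged[key]!r}")
    params = ModelParameters(
        beta=float(merged["beta"]),
        gamma=float(merged["gamma"]),
        delta=float(merged["delta"]),
        alpha=float(merged["alpha"]),
        mu=float(merged["mu"]),
        n_total=float(merged["n_total"]),
    )
    init = tuple(float(x) for x in merged["init"])
    if len(init) != 4:
        raise InvalidStateError(f"init must have 4 components, got {len(init)}")
    if merged["kind"] == "deterministic":
        total = sum(init)
        if abs(total - 1.0) > 1e-6 or min(init) < 0:
            raise InvalidStateError(
                f"scaled init {init!r} must be nonnegative and sum to 1 (sum {total:g})"
            )
    weights = ControlWeights(**merged["weights"])
    return ScenarioPreset(
        name=str(merged.get("name", name)),
        params=params,
        init=init,
        t_final=float(merged["t_final"]),
        kind=str(merged["kind"]),
        control_mode=str(merged["control_mode"]),
        weights=weights,
        seed=int(merged["seed"]),
        sweep_field=merged.get("sweep_field"),
        sweep_values=tuple(merged.get("sweep_values", ())),
        n_reps=int(merged["n_reps"]),
    )


def load_config(path: str | Path) -> ScenarioPreset:
    """Parse a YAML or JSON scenario file, filling defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidStateError(f"config {path} did not parse to a mapping")
    return preset_from_dict(data, name=path.stem)


def write_config(preset: ScenarioPreset, path: str | Path) -> Path:
    """Serialise a preset to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    data = preset_to_dict(preset)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
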