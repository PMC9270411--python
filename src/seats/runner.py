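"""Scenario dispatch: run a preset end to end and write its artifacts.

Each run produces one or more trajectory CSVs (``time,s,e,v,z`` for scaled
runs, ``time,S,E,A,T[,u1,u2]`` for count/control runs), a summary JSON
with the derived quantities (R0, equilibria, stability verdicts, J), and
optionally PNG line plots.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .config import preset_to_dict
from .control import scenario_compare
from .model import (
    analyze,
    simulate,
)
from .presets import ScenarioPreset
from .stability import certify_endemic_global_stability, classify_local_stability
from .stochastic import gillespie_simulate
from .params import ModelParameters

logger = logging.getLogger("seats")

_FLOAT_FMT = "%.10g"


@dataclass
class RunRecord:
    """Resolved configuration plus the artifacts a run produced."""

    config: dict
    version: str
    timestamp: str
    outputs: list[str] = field(default_factory=list)
    derived: dict = field(default_factory=dict)


def _write_csv(path: Path, times, states, columns, controls=None) -> None:
    import pandas as pd

    frame = pd.DataFrame(states, columns=columns)
    frame.insert(0, "time", times)
    if controls is not None:
        frame["u1"] = controls.u1
        frame["u2"] = controls.u2
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _maybe_plot(path: Path, times, states, columns) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for j, name in enumerate(columns):
        ax.plot(times, states[:, j], label=name)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("compartment")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _analysis_summary(params: ModelParameters) -> dict:
    summary = analyze(params)
    out = {
        "r0": summary.r0,
        "dfe": list(summary.dfe),
        "endemic_exists": summary.endemic_exists,
        "dfe_stability": classify_local_stability(summary.dfe, params).verdict,
    }
    if summary.endemic is not None:
        out["endemic"] = list(summary.endemic)
        out["endemic_stability"] = classify_local_stability(summary.endemic, params).verdict
        if summary.r0 > 1:
            out["endemic_vl_certified"] = bool(
                certify_endemic_global_stability(params).certified
            )
    return out


def run_scenario(
    preset: ScenarioPreset,
    out_dir: str | Path = ".",
    seed: int | None = None,
    plot: bool = False,
) -> RunRecord:
    """Execute one preset and write its CSV/JSON (and optional PNG) output."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = preset.seed if seed is None else seed
    record = RunRecord(
        config=preset_to_dict(preset),
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    logger.info("scenario %s (%s): config resolved", preset.name, preset.kind)

    if preset.kind == "deterministic":
        traj = simulate(preset.params, preset.init, preset.t_final)
        csv_path = out_dir / f"{preset.name}_trajectory.csv"
        _write_csv(csv_path, traj.times, traj.states, ["s", "e", "v", "z"])
        record.outputs.append(str(csv_path))
        record.derived = _analysis_summary(preset.params)
        record.derived["final_state"] = traj.final_state.tolist()
        if plot:
            png = out_dir / f"{preset.name}.png"
            _maybe_plot(png, traj.times, traj.states, ["s", "e", "v", "z"])
            record.outputs.append(str(png))

    elif preset.kind == "sweep":
        record.derived = {"sweep_field": preset.sweep_field, "runs": []}
        for value in preset.sweep_values:
            params = preset.params.with_(**{preset.sweep_field: value})
            traj = simulate(params, preset.init, preset.t_final)
            csv_path = out_dir / f"{preset.name}_{preset.sweep_field}_{value:g}.csv"
            _write_csv(csv_path, traj.times, traj.states, ["s", "e", "v", "z"])
            record.outputs.append(str(csv_path))
            record.derived["runs"].append(
                {preset.sweep_field: value, "r0": analyze(params).r0}
            )

    elif preset.kind == "stochastic":
        counts = tuple(x * preset.params.n_total for x in preset.init)
        for rep in range(preset.n_reps):
            traj = gillespie_simulate(
                preset.params, counts, preset.t_final, rng_seed=seed + rep
            )
            csv_path = out_dir / f"{preset.name}_rep{rep:03d}.csv"
            _write_csv(csv_path, traj.times, traj.states, ["S", "E", "A", "T"])
            record.outputs.append(str(csv_path))
        record.derived = _analysis_summary(preset.params)
        record.derived["n_reps"] = preset.n_reps

    elif preset.kind == "control":
        comparison = scenario_compare(
            preset.params,
            preset.init,
            preset.weights,
            preset.t_final,
            mode=preset.control_mode,
        )
        sol = comparison.solution
        csv_path = out_dir / f"{preset.name}_controlled.csv"
        _write_csv(
            csv_path,
            sol.trajectory.times,
            sol.trajectory.states,
            ["S", "E", "A", "T"],
            controls=sol.controls,
        )
        base_path = out_dir / f"{preset.name}_uncontrolled.csv"
        _write_csv(
            base_path,
            comparison.uncontrolled.trajectory.times,
            comparison.uncontrolled.trajectory.states,
            ["S", "E", "A", "T"],
        )
        record.outputs += [str(csv_path), str(base_path)]
        record.derived = {
            "mode": preset.control_mode,
            "j_controlled": comparison.j_controlled,
            "j_uncontrolled": comparison.j_uncontrolled,
            "converged": sol.converged,
            "n_sweeps": len(sol.iterations),
            "terminal_A_controlled": float(sol.trajectory.states[-1, 2]),
            "terminal_A_uncontrolled": float(
                comparison.uncontrolled.trajectory.states[-1, 2]
            ),
        }
        if plot:
            png = out_dir / f"{preset.name}.png"
            _maybe_plot(
                png, sol.trajectory.times, sol.trajectory.states, ["S", "E", "A", "T"]
            )
            record.outputs.append(str(png))
    else:
        raise ValueError(f"unknown scenario kind {preset.kind!r}")

    summary_path = out_dir / f"{preset.name}_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "config": record.config,
                "version": record.version,
                "timestamp": record.timestamp,
                "derived": record.derived,
                "outputs": record.outputs,
            },
            indent=2,
            default=float,
        )
    )
    record.outputs.append(str(summary_path))
    logger.info(
        "scenario %s done: %d output files, derived keys %s",
        preset.name,
        len(record.outputs),
        sorted(record.derived),
    )
    return record
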