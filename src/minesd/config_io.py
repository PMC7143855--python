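"""Configuration loading, result serialization, run manifests.

A run is configured by a single YAML (or JSON — valid JSON is valid YAML)
file with up to five sections::

    params:      # production constants, budget, initial stocks
      dust: 3310
    options:     # removal_basis: stock|literal, unit_harmonization: on|off
      removal_basis: stock
    simulation:  # initial_time, final_time, dt
      final_time: 24
    allocation:  # a custom policy for `run --case custom`
      p_air: 0.2
    scenarios:   # override of the default six-case table
      - {case: 1, p_air: 0.4, p_solid: 0.15, ...}

Every field is optional; an empty file reproduces the built-in defaults
(budget 50, 24 months, dt 1, the tabulated constants).  Unknown keys warn,
invalid values raise a :class:`ConfigError` listing all violations at once.
All output is plain text (CSV / JSON).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from . import __version__
from .engine import SimConfig, Trajectory
from .experiments import RankingReport, ScenarioResult, ScenarioTable, default_scenarios
from .mine import SUBSYSTEM_STOCKS, AllocationPolicy, MineModelConfig, MineParams

__all__ = [
    "ConfigError",
    "LoadedConfig",
    "RunManifest",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_ranking_report",
]

_SECTIONS = ("params", "options", "allocation", "simulation", "scenarios")
_SIM_KEYS = ("initial_time", "final_time", "dt", "method")
_OPTION_KEYS = ("removal_basis", "unit_harmonization")
_POLICY_KEYS = ("p_air", "p_solid", "p_water", "p_green", "p_land")


class ConfigError(ValueError):
    """Invalid configuration; ``messages`` lists every violation."""

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.messages))


@dataclass
class LoadedConfig:
    """Everything a run needs: model config, scenario table, grid, custom policy."""

    model: MineModelConfig
    scenarios: ScenarioTable
    sim: SimConfig
    allocation: AllocationPolicy | None = None
    source: str = "builtin"


def _pydantic_messages(prefix: str, exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{prefix}{loc}: {err['msg']}")
    return out


def _warn_unknown(mapping: dict, allowed, context: str) -> None:
    for key in mapping:
        if key not in allowed:
            warnings.warn(f"unknown key {key!r} in {context}", stacklevel=3)


def load_config(path: str | Path | None = None) -> LoadedConfig:
    """Load a run configuration, filling every omitted field from the defaults."""
    if path is None:
        return LoadedConfig(
            model=MineModelConfig(),
            scenarios=default_scenarios(),
            sim=SimConfig(),
            source="builtin",
        )
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"cannot parse {path}: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    _warn_unknown(raw, _SECTIONS, str(path))

    errors: list[str] = []

    params_raw = raw.get("params") or {}
    known_params = set(MineParams.model_fields) | {"land_area", "Land area"}
    _warn_unknown(params_raw, known_params, "params")
    params_raw = {k: v for k, v in params_raw.items() if k in known_params}

    options_raw = raw.get("options") or {}
    _warn_unknown(options_raw, _OPTION_KEYS, "options")
    options_raw = {k: v for k, v in options_raw.items() if k in _OPTION_KEYS}

    model = None
    try:
        model = MineModelConfig(params=params_raw, **options_raw)
    except ValidationError as exc:
        errors += _pydantic_messages("", exc)

    sim_raw = raw.get("simulation") or {}
    _warn_unknown(sim_raw, _SIM_KEYS, "simulation")
    sim = None
    try:
        sim = SimConfig(**{k: v for k, v in sim_raw.items() if k in _SIM_KEYS})
    except (ValueError, TypeError) as exc:
        errors.append(f"simulation: {exc}")

    allocation = None
    if raw.get("allocation") is not None:
        alloc_raw = raw["allocation"]
        _warn_unknown(alloc_raw, _POLICY_KEYS, "allocation")
        try:
            allocation = AllocationPolicy(
                **{k: v for k, v in alloc_raw.items() if k in _POLICY_KEYS}
            )
        except ValidationError as exc:
            errors += _pydantic_messages("allocation.", exc)

    scenarios = default_scenarios()
    if raw.get("scenarios") is not None:
        cases = []
        for i, entry in enumerate(raw["scenarios"]):
            if not isinstance(entry, dict) or "case" not in entry:
                errors.append(f"scenarios[{i}]: each entry needs a 'case' id")
                continue
            _warn_unknown(entry, ("case", *_POLICY_KEYS), f"scenarios[{i}]")
            try:
                policy = AllocationPolicy(
                    **{k: v for k, v in entry.items() if k in _POLICY_KEYS}
                )
                cases.append((int(entry["case"]), policy))
            except ValidationError as exc:
                errors += _pydantic_messages(f"scenarios[{i}].", exc)
        if not errors:
            try:
                scenarios = ScenarioTable(cases=tuple(cases))
            except ValueError as exc:
                errors.append(f"scenarios: {exc}")

    if errors:
        raise ConfigError(errors)
    return LoadedConfig(
        model=model, scenarios=scenarios, sim=sim, allocation=allocation, source=str(path)
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """CSV with a leading ``time`` column, variables in declaration order.

    Values are written at full ``repr`` precision so a read-back round-trips.
    """
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    times = df["time"].to_numpy(dtype=float)
    series = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time"}
    return Trajectory(times=times, series=series)


@dataclass
class RunManifest:
    """Provenance record serialized next to every output."""

    source: str
    sim: dict
    options: dict
    version: str = __version__
    created: str | None = None

    @classmethod
    def from_run(
        cls, loaded: LoadedConfig, timestamp: bool = True, **extra_options
    ) -> "RunManifest":
        options = {
            "removal_basis": loaded.model.removal_basis,
            "unit_harmonization": loaded.model.unit_harmonization,
        }
        options.update(extra_options)
        return cls(
            source=loaded.source,
            sim=dataclasses.asdict(loaded.sim),
            options=options,
            created=(
                datetime.datetime.now(datetime.timezone.utc).isoformat()
                if timestamp
                else None
            ),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def write_ranking_report(
    report: RankingReport, results: list[ScenarioResult], path: str | Path
) -> None:
    """One CSV row per case: id, final overall quality, rank, final stocks."""
    rank_of = {cid: i + 1 for i, cid in enumerate(report.ordering)}
    rows = []
    for r in sorted(results, key=lambda r: r.case_id):
        row = {
            "case_id": r.case_id,
            "overall_quality": report.overall_quality[r.case_id],
            "rank": rank_of[r.case_id],
        }
        for sub, stock in SUBSYSTEM_STOCKS.items():
            row[f"final_{stock}"] = float(r.trajectory.series[stock][-1])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
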