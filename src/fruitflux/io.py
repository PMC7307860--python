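"""Configuration loading, report writing and observation-series I/O.

All artifacts are plain text: comma-separated CSV with a header row, dot
decimals and UTF-8; hours are time-of-day values on a 0–23 grid.  Floats
are serialized at full repr precision, so a write→read round trip is
exact.  Every report carries a manifest with the seed and a hash of the
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .drivers import (
    FullDaySinusoid,
    ScenarioInputs,
    SinusoidDriver,
    scenario_preset,
    symplast_potential_driver,
)
from .model_core import SCENARIO_LABELS, ModelParameters, reference_parameters
from .simulate import FlowPatternSummary, SimulationResult
from .synthetic_data import ObservationSeries

__all__ = [
    "DataError",
    "load_scenario",
    "load_parameters",
    "write_report",
    "read_timeseries",
    "write_observations",
    "read_observations",
    "config_hash",
]


class DataError(ValueError):
    """Malformed or inconsistent input data / configuration."""


_SCENARIO_REQUIRED = {"label", "condition", "psi_w_pp", "c_pp_mass",
                      "transpiration_per_area", "psi_fs_night"}
_SCENARIO_OPTIONAL = {"treatment", "temperature"}


def _as_driver(spec, field: str) -> SinusoidDriver:
    try:
        return SinusoidDriver(base_value=float(spec["base"]),
                              extreme_value=float(spec["extreme"]))
    except (KeyError, TypeError) as exc:
        raise DataError(f"field '{field}' must map 'base' and 'extreme'") from exc


def load_scenario(name_or_path: str | Path,
                  params: ModelParameters | None = None) -> ScenarioInputs:
    """Resolve a scenario: one of the six named presets, or a YAML/JSON
    file describing the drivers.

    A file must provide ``label``, ``condition`` (control|girdled),
    ``psi_w_pp`` and ``c_pp_mass`` (mappings with ``base`` / ``extreme``),
    ``transpiration_per_area`` (``min`` / ``max``) and ``psi_fs_night``
    (negative MPa); ``treatment`` and ``temperature`` are optional.
    Unknown keys are rejected.
    """
    name = str(name_or_path)
    if name in SCENARIO_LABELS:
        return scenario_preset(name, params)
    path = Path(name_or_path)
    if not path.exists():
        raise DataError(
            f"{name!r} is neither a preset ({', '.join(SCENARIO_LABELS)}) "
            "nor an existing scenario file")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise DataError(f"{path}: scenario file must be a mapping")
    unknown = set(raw) - _SCENARIO_REQUIRED - _SCENARIO_OPTIONAL
    if unknown:
        raise DataError(f"{path}: unknown keys {sorted(unknown)}")
    missing = _SCENARIO_REQUIRED - set(raw)
    if missing:
        raise DataError(f"{path}: missing required field(s) {sorted(missing)}")
    tr = raw["transpiration_per_area"]
    try:
        transpiration = FullDaySinusoid(min_value=float(tr["min"]),
                                        max_value=float(tr["max"]))
    except (KeyError, TypeError) as exc:
        raise DataError(
            f"{path}: field 'transpiration_per_area' must map 'min' and 'max'"
        ) from exc
    try:
        return ScenarioInputs(
            label=str(raw["label"]),
            treatment=str(raw.get("treatment", "custom")),
            condition=str(raw["condition"]),
            psi_w_pp=_as_driver(raw["psi_w_pp"], "psi_w_pp"),
            c_pp_mass=_as_driver(raw["c_pp_mass"], "c_pp_mass"),
            transpiration_per_area=transpiration,
            psi_w_fs=symplast_potential_driver(float(raw["psi_fs_night"])),
            temperature=float(raw.get("temperature", 293.15)),
        )
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def load_parameters(path: str | Path) -> ModelParameters:
    """Parameter set from a YAML/JSON mapping; unspecified fields keep the
    reference calibration values."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise DataError(f"{path}: parameter file must be a mapping")
    base = reference_parameters()
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    try:
        return dataclasses.replace(base, **raw)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: {exc}") from exc


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_hash(obj) -> str:
    """Stable sha256 of a configuration object (first 12 hex digits)."""
    payload = json.dumps(_to_jsonable(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_report(result: SimulationResult, summary: FlowPatternSummary | None,
                 outdir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write a simulation report: tidy ``timeseries.csv`` (hour, variable,
    value), ``summary.json`` and ``run.log``.  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wide = result.frame()
    wide["nonphysical"] = wide["nonphysical"].astype(float)  # keep CSV numeric
    tidy = wide.melt(id_vars="hour", var_name="variable", value_name="value")
    tidy = tidy.sort_values(["variable", "hour"], kind="stable")
    csv_path = outdir / "timeseries.csv"
    # 17 significant digits: exact binary64 round trip
    tidy.to_csv(csv_path, index=False, float_format="%.17g")

    meta = {
        "scenario": result.config.scenario.label,
        "condition": result.config.scenario.condition,
        "W0": result.config.W0,
        "reference_hour": result.config.reference_hour,
        "timestep": result.config.timestep,
        "seed": seed,
        "config_hash": config_hash(result.config),
        "params": _to_jsonable(result.config.params),
    }
    payload = {"meta": meta,
               "summary": summary.as_dict() if summary is not None else None}
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    log_path = outdir / "run.log"
    lines = [f"scenario={meta['scenario']} hash={meta['config_hash']} seed={seed}"]
    for state, hour in zip(result.states, result.hours):
        status = "WARN nonphysical" if state.nonphysical else "ok"
        lines.append(f"INFO hour {hour:05.2f}: {status}")
    log_path.write_text("\n".join(lines) + "\n")
    return {"timeseries": csv_path, "summary": json_path, "log": log_path}


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a tidy report CSV back into the wide per-hour table."""
    tidy = pd.read_csv(path, float_precision="round_trip")
    for col in ("hour", "variable", "value"):
        if col not in tidy.columns:
            raise DataError(f"{path}: missing column '{col}'")
    wide = tidy.pivot(index="hour", columns="variable", values="value")
    wide = wide.reset_index().rename_axis(None, axis=1)
    if "nonphysical" in wide:
        wide["nonphysical"] = wide["nonphysical"].astype(bool)
    return wide


_OBS_COLUMNS = ["fruit_id", "scenario", "condition", "hour",
                "diameter_mm", "weight_g"]


def write_observations(series: Iterable[ObservationSeries], path: str | Path,
                       manifest: Mapping | None = None) -> Path:
    """Observation series to CSV (one row per fruit-hour); an optional
    manifest JSON (config + seed) is written alongside."""
    path = Path(path)
    rows = []
    for s in series:
        for h, d, w in zip(s.hours, s.diameter_mm, s.weight_g):
            rows.append((s.fruit_id, s.scenario, s.condition, h, d, w))
    pd.DataFrame(rows, columns=_OBS_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.17g")
    if manifest is not None:
        Path(path.with_suffix(".manifest.json")).write_text(
            json.dumps(_to_jsonable(manifest), indent=2, sort_keys=True))
    return path


def read_observations(path: str | Path) -> list[ObservationSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    out = []
    for fruit_id, grp in df.groupby("fruit_id", sort=True):
        grp = grp.sort_values("hour")
        out.append(ObservationSeries(
            fruit_id=str(fruit_id),
            scenario=str(grp["scenario"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
            hours=grp["hour"].to_numpy(dtype=float),
            diameter_mm=grp["diameter_mm"].to_numpy(dtype=float),
            weight_g=grp["weight_g"].to_numpy(dtype=float),
        ))
    return out
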