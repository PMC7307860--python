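"""Hourly quasi-steady-state simulation of a day and flow diagnostics.

Within each time step the vascular network is assumed to carry steady
flows (no storage), so the day is a sequence of independent algebraic
solves driven by the diurnal inputs.  Fresh weight is then integrated from
the symplast water and sugar inflows,

    W(h) = W(h0) + Σ_i (U_fa_fs,i + S_fa_fs,i) Δi,

anchored at a reference hour (09.00 by default); hours before the anchor
are filled by backward accumulation so W(h0) is exactly the supplied
initial weight.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .drivers import (
    ScenarioInputs,
    geometry_from_weight,
    relative_variation,
)
from .model_core import (
    FruitGeometry,
    ModelParameters,
    NonPhysicalSolutionWarning,
    SingularSystemError,
    SteadyState,
    _assemble_arrays,
    _derive_state,
    _solve_girdled_arrays,
    _solve_linear,
    _state_from_fields,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "FlowPatternSummary",
    "run_day",
    "summarize_flows",
    "summarize_frame",
    "classify_pattern",
    "input_sweep",
]

NIGHT_START, NIGHT_END = 18.0, 6.0     # the constant-driver window
MIDDAY_WINDOW = (10.0, 14.0)

_FLOW_COLUMNS = (
    "psi_p_fp", "psi_p_fa", "C_fp", "C_fa", "psi_w_fp", "psi_w_fa",
    "U_px_fx", "U_pp_fp", "U_fx_fa", "U_fp_fa", "U_fa_fs", "U_fx_fp",
    "S_pp_fp", "S_fp_fa", "S_fa_fs",
)


@dataclass(frozen=True)
class SimulationConfig:
    """One day of simulation: scenario drivers, parameters, initial fresh
    weight ``W0`` (g, defined at ``reference_hour``), time step (h) and
    duration (h).  ``update_geometry_hourly`` recomputes the surface area
    from the evolving weight by fixed-point iteration; by default geometry
    is frozen at W0 for the whole day (dry weight always is)."""

    scenario: ScenarioInputs
    params: ModelParameters
    W0: float
    reference_hour: float = 9.0
    timestep: float = 1.0
    duration: float = 24.0
    update_geometry_hourly: bool = False

    def __post_init__(self) -> None:
        if self.W0 <= 0:
            raise ValueError("W0 must be positive")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        n = self.duration / self.timestep
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("duration must be a positive multiple of timestep")


@dataclass
class SimulationResult:
    hours: np.ndarray                  # time-of-day grid, h
    states: list[SteadyState]
    weight: np.ndarray                 # fresh weight, g
    water_stored: np.ndarray           # cumulative symplast water since h0, g
    sugar_stored: np.ndarray           # cumulative symplast sugar since h0, g
    T_fa: np.ndarray                   # transpiration, g h⁻¹
    config: SimulationConfig = field(repr=False)

    def frame(self) -> pd.DataFrame:
        """Wide per-hour table of all solved and integrated quantities."""
        data = {"hour": self.hours}
        for name in _FLOW_COLUMNS:
            data[name] = np.array([getattr(s, name) for s in self.states])
        data["nonphysical"] = np.array([s.nonphysical for s in self.states])
        data["T_fa"] = self.T_fa
        data["weight"] = self.weight
        data["water_stored"] = self.water_stored
        data["sugar_stored"] = self.sugar_stored
        return pd.DataFrame(data)


def _solve_day_arrays(scenario: ScenarioInputs, params: ModelParameters,
                      geom: FruitGeometry, hours: np.ndarray):
    """Solve every hour at fixed geometry; returns (fields dict, T_fa)."""
    psi_pp = np.asarray(scenario.psi_w_pp(hours), dtype=float)
    c_mass = np.asarray(scenario.c_pp_mass(hours), dtype=float)
    C_pp = c_mass / params.constants.M_S
    T_fa = np.asarray(scenario.transpiration_per_area(hours), dtype=float) * geom.A_f
    psi_fs = np.asarray(scenario.psi_w_fs(hours), dtype=float)
    temp = np.array([scenario.temperature_at(h) for h in hours]) \
        if scenario.hourly_temperature is not None else scenario.temperature

    if scenario.condition == "girdled":
        fields = _solve_girdled_arrays(psi_pp, T_fa, psi_fs, params, geom)
    else:
        A, b = _assemble_arrays(psi_pp, C_pp, T_fa, psi_fs, temp, params, geom)
        try:
            x = _solve_linear(A, b)
        except SingularSystemError:
            for i, h in enumerate(hours):   # locate the offending hour
                try:
                    _solve_linear(A[i], b[i])
                except SingularSystemError as exc:
                    raise SingularSystemError(
                        f"steady-state solve failed at hour {h:g}: {exc}"
                    ) from exc
            raise
        fields = _derive_state(x, psi_pp, C_pp, T_fa, psi_fs, temp, params, geom)
    return fields, T_fa


def _integrate_weight(fields: dict, hours: np.ndarray, W0: float,
                      reference_hour: float, dt: float):
    inflow = fields["U_fa_fs"] + fields["S_fa_fs"]
    # c[i] = accumulated inflow from the grid start up to (not incl.) hour i
    c = np.concatenate([[0.0], np.cumsum(inflow) * dt])[:-1]
    tod = np.mod(hours, 24.0)
    anchors = np.flatnonzero(np.isclose(tod, reference_hour % 24.0))
    if anchors.size == 0:
        raise ValueError(
            f"reference hour {reference_hour:g} is not on the simulation grid"
        )
    i0 = int(anchors[0])
    weight = W0 + c - c[i0]
    # storage tallies relative to the anchor, matching the weight anchoring
    water = np.concatenate([[0.0], np.cumsum(fields["U_fa_fs"]) * dt])[:-1]
    sugar = np.concatenate([[0.0], np.cumsum(fields["S_fa_fs"]) * dt])[:-1]
    return weight, water - water[i0], sugar - sugar[i0]


def run_day(config: SimulationConfig) -> SimulationResult:
    """Simulate ``config.duration`` hours at ``config.timestep`` resolution.

    Solves the hourly steady state (control or girdled according to the
    scenario), integrates fresh weight from the anchor hour, and reports
    hours with non-physical (negative-concentration) solutions through a
    single :class:`NonPhysicalSolutionWarning`.
    """
    dt = config.timestep
    n = int(round(config.duration / dt))
    hours = np.arange(n) * dt
    geom = geometry_from_weight(config.W0)

    fields, T_fa = _solve_day_arrays(config.scenario, config.params, geom, hours)
    weight, water, sugar = _integrate_weight(
        fields, hours, config.W0, config.reference_hour, dt)

    if config.update_geometry_hourly:
        # geometry follows the evolving weight; iterate to a fixed point
        for _ in range(50):
            prev = weight
            per_hour = []
            for w, h in zip(weight, hours):
                g = geometry_from_weight(max(w, 1e-6))
                g = dataclasses.replace(g, DW=geom.DW)  # DW fixed per day
                per_hour.append(_solve_day_arrays(
                    config.scenario, config.params, g, np.asarray([h])))
            fields = {k: np.concatenate([f[0][k] for f in per_hour])
                      for k in per_hour[0][0]}
            T_fa = np.concatenate([f[1] for f in per_hour])
            weight, water, sugar = _integrate_weight(
                fields, hours, config.W0, config.reference_hour, dt)
            if np.max(np.abs(weight - prev)) < 1e-10:
                break

    states = [_state_from_fields(fields, idx=i) for i in range(n)]
    bad = [float(hours[i]) for i, s in enumerate(states) if s.nonphysical]
    if bad:
        warnings.warn(
            f"negative sugar concentration solved at hours {bad}",
            NonPhysicalSolutionWarning,
            stacklevel=2,
        )
    return SimulationResult(hours=hours, states=states, weight=weight,
                            water_stored=water, sugar_stored=sugar,
                            T_fa=T_fa, config=config)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowPatternSummary:
    """Diurnal flow-pattern statistics for one simulated day.

    Inflow fractions are computed on the positive parts of the pathway
    flows integrated over the day (backflow goes to the outflow tallies).
    The night recirculation fraction is the mean over 18.00–06.00 h of the
    phloem→xylem lateral transfer divided by the pedicel→fruit phloem
    inflow.  Relative variations use the diurnal functionals
    |(max−min)/max| (symplast water inflow) and |(max−min)/min| (sugar
    uptake and the two fruit sugar concentrations).  Undefined ratios are
    reported as None, never coerced to zero.
    """

    phloem_inflow_fraction: float | None
    xylem_inflow_fraction: float | None
    phloem_outflow_total: float
    xylem_backflow_total: float
    backflow_hours: tuple[float, ...]
    night_recirculation_fraction: float | None
    relvar_symplast_inflow: float | None
    relvar_sugar_uptake: float | None
    relvar_c_fp: float | None
    relvar_c_fa: float | None
    dry_mass_gain: float
    mean_xylem_to_phloem: float

    def as_dict(self) -> dict:
        d = asdict(self)
        d["backflow_hours"] = list(d["backflow_hours"])
        return d


def _is_night(hours: np.ndarray) -> np.ndarray:
    tod = np.mod(hours, 24.0)
    return (tod >= NIGHT_START) | (tod < NIGHT_END)


def _safe_relvar(values, denominator):
    try:
        return relative_variation(values, denominator)
    except ZeroDivisionError:
        return None


def summarize_flows(result: SimulationResult) -> FlowPatternSummary:
    """Flow-pattern diagnostics over a full simulated day (requires a
    result covering at least 24 h)."""
    return summarize_frame(result.frame(), result.config.timestep)


def summarize_frame(df: pd.DataFrame, timestep: float = 1.0) -> FlowPatternSummary:
    """Same diagnostics computed from a per-hour table (e.g. one read back
    from a report CSV); needs the ``hour`` and flow columns."""
    hours = df["hour"].to_numpy(dtype=float)
    dt = timestep
    if hours.size * dt < 24.0:
        raise ValueError("summary requires a full 24 h simulation")

    upx, upp = df["U_px_fx"].to_numpy(), df["U_pp_fp"].to_numpy()
    uxp = df["U_fx_fp"].to_numpy()

    phloem_in = upp[upp > 0].sum() * dt
    xylem_in = upx[upx > 0].sum() * dt
    total_in = phloem_in + xylem_in
    if total_in > 0:
        f_p, f_x = float(phloem_in / total_in), float(xylem_in / total_in)
    else:
        f_p = f_x = None

    night = _is_night(hours)
    valid = night & (upp != 0)
    recirc = float(np.mean(-uxp[valid] / upp[valid])) if valid.any() else None

    return FlowPatternSummary(
        phloem_inflow_fraction=f_p,
        xylem_inflow_fraction=f_x,
        phloem_outflow_total=float(-upp[upp < 0].sum() * dt + 0.0),
        xylem_backflow_total=float(-upx[upx < 0].sum() * dt + 0.0),
        backflow_hours=tuple(float(h) for h in hours[upx < 0]),
        night_recirculation_fraction=recirc,
        relvar_symplast_inflow=_safe_relvar(df["U_fa_fs"], "max"),
        relvar_sugar_uptake=_safe_relvar(df["S_fa_fs"], "min"),
        relvar_c_fp=_safe_relvar(df["C_fp"], "min"),
        relvar_c_fa=_safe_relvar(df["C_fa"], "min"),
        dry_mass_gain=float(df["S_fa_fs"].sum() * dt * 24.0
                            / (hours.size * dt)),
        mean_xylem_to_phloem=float(uxp.mean()),
    )


def classify_pattern(result: SimulationResult, hour: float) -> str:
    """Label the flow pattern at one solved hour from the signs of the
    pedicel-xylem inflow and the lateral xylem↔phloem transfer:
    ``night-type`` (xylem inflow, phloem→xylem transfer), ``midday-type``
    (xylem backflow, xylem→phloem transfer), else ``transitional``."""
    idx = np.flatnonzero(np.isclose(result.hours, hour))
    if idx.size == 0:
        raise ValueError(f"hour {hour:g} was not solved")
    s = result.states[int(idx[0])]
    if s.U_px_fx > 0 and s.U_fx_fp < 0:
        return "night-type"
    if s.U_px_fx < 0 and s.U_fx_fp > 0:
        return "midday-type"
    return "transitional"


def input_sweep(config: SimulationConfig, variable: str,
                levels: Sequence[float]) -> pd.DataFrame:
    """Re-run the day at scaled input levels and tabulate the summaries.

    ``variable='C_pp'`` scales the whole pedicel sugar-concentration driver
    (base and midday extreme) by each level; ``variable='psi_w_pp'`` scales
    only the midday minimum of the pedicel water potential, probing deeper
    midday water stress at an unchanged night base.
    """
    if len(levels) < 2:
        raise ValueError("a sweep needs at least two levels")
    rows = []
    for level in levels:
        scn = config.scenario
        if variable == "C_pp":
            scn = replace(scn, c_pp_mass=scn.c_pp_mass.scaled(level, level))
        elif variable == "psi_w_pp":
            scn = replace(scn, psi_w_pp=scn.psi_w_pp.scaled(1.0, level))
        else:
            raise ValueError("variable must be 'C_pp' or 'psi_w_pp'")
        res = run_day(replace(config, scenario=scn))
        row = {"level": float(level), "variable": variable}
        row.update(summarize_flows(res).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
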