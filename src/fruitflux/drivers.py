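"""Diurnal input drivers and fruit allometry.

The external drivers of the model (pedicel water potential, pedicel phloem
sugar concentration, fruit symplast water potential) are flat at a base
value during the night (18.00–06.00 h) and follow a sine of 24 h period
inside the 06.00–18.00 h window, peaking (or dipping) at 12.00 h.  Fruit
transpiration per unit area is a full-day sinusoid with its minimum at
05.00 h and maximum at 17.00 h.

Allometric relations for 'Suncrest' peach link diameter D (mm), fresh
weight W (g) and surface area A_f (cm²):

    W = 0.003 · D^2.58        A_f = 6.049 · W^0.601

and the dry weight is taken as a fixed fraction (10%) of the daily mean
fresh weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .constants import M_SUCROSE
from .model_core import (
    BoundaryConditions,
    FruitGeometry,
    ModelParameters,
    REFERENCE_DUAL_CONDUCTANCES,
    REFERENCE_PSI_FS_NIGHT,
    SCENARIO_LABELS,
    mass_fraction_to_molar,
    reference_parameters,
)

__all__ = [
    "SinusoidDriver",
    "FullDaySinusoid",
    "ScenarioInputs",
    "scenario_preset",
    "preset_initial_weight",
    "geometry_from_weight",
    "geometry_from_diameter",
    "reference_geometry",
    "relative_variation",
    "WEIGHT_COEF",
    "WEIGHT_EXP",
    "AREA_COEF",
    "AREA_EXP",
    "DRY_WEIGHT_FRACTION",
]

PERIOD_H = 24.0

# 'Suncrest' allometry coefficients
WEIGHT_COEF, WEIGHT_EXP = 0.003, 2.58     # W = 0.003 D^2.58  (W g, D mm)
AREA_COEF, AREA_EXP = 6.049, 0.601        # A_f = 6.049 W^0.601 (cm²)
DRY_WEIGHT_FRACTION = 0.10


def _wrap_hour(hour):
    hour = np.asarray(hour, dtype=float)
    if not np.all(np.isfinite(hour)):
        raise ValueError("hour must be finite")
    return np.mod(hour, PERIOD_H)


@dataclass(frozen=True)
class SinusoidDriver:
    """Windowed diurnal driver: constant ``base_value`` outside
    [window_start, window_end], a 24 h-period sine inside it that reaches
    ``extreme_value`` at ``extreme_hour`` and rejoins the base continuously
    at both window edges.

    Continuity forces the window to span half a period (12 h) and the
    extreme to sit a quarter period (6 h) after the window opens; the
    constructor enforces both.
    """

    base_value: float
    extreme_value: float
    extreme_hour: float = 12.0
    window_start: float = 6.0
    window_end: float = 18.0

    def __post_init__(self) -> None:
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        if not math.isclose(self.window_end - self.window_start, PERIOD_H / 2):
            raise ValueError("window must span 12 h for boundary continuity")
        if not math.isclose(self.extreme_hour, self.window_start + PERIOD_H / 4):
            raise ValueError("extreme_hour must be 6 h after window_start")

    def __call__(self, hour):
        h = _wrap_hour(hour)
        phase = np.sin(2 * np.pi * (h - self.window_start) / PERIOD_H)
        inside = (h >= self.window_start) & (h <= self.window_end)
        out = np.where(inside,
                       self.base_value + (self.extreme_value - self.base_value) * phase,
                       self.base_value)
        return out.item() if out.ndim == 0 else out

    def scaled(self, base_factor: float = 1.0, extreme_factor: float = 1.0
               ) -> "SinusoidDriver":
        return replace(self, base_value=self.base_value * base_factor,
                       extreme_value=self.extreme_value * extreme_factor)


@dataclass(frozen=True)
class FullDaySinusoid:
    """Whole-day sinusoid between ``min_value`` (at ``min_hour``) and
    ``max_value`` (at ``max_hour``); the two extrema must be half a period
    apart.  Used for the transpiration rate per unit area."""

    min_value: float
    max_value: float
    min_hour: float = 5.0
    max_hour: float = 17.0

    def __post_init__(self) -> None:
        if not math.isclose((self.max_hour - self.min_hour) % PERIOD_H,
                            PERIOD_H / 2):
            raise ValueError("extrema must be 12 h apart")

    def __call__(self, hour):
        h = _wrap_hour(hour)
        mean = 0.5 * (self.min_value + self.max_value)
        amp = 0.5 * (self.max_value - self.min_value)
        out = mean + amp * np.sin(2 * np.pi * (h - (self.max_hour - PERIOD_H / 4))
                                  / PERIOD_H)
        return out.item() if out.ndim == 0 else out


# driver presets printed for the field campaigns --------------------------------

_PSI_PP = SinusoidDriver(base_value=-0.5, extreme_value=-1.3)
_TRANSPIRATION = FullDaySinusoid(min_value=2.74e-4, max_value=2.63e-3)
_C_PP = {
    "30": SinusoidDriver(base_value=0.12, extreme_value=0.28),
    "5": SinusoidDriver(base_value=0.08, extreme_value=0.24),
}


def symplast_potential_driver(psi_night: float) -> SinusoidDriver:
    """Symplast water potential: flat ``psi_night`` at night, dipping to
    1.2 × ``psi_night`` at 12.00 h."""
    if psi_night >= 0:
        raise ValueError("psi_night must be negative")
    return SinusoidDriver(base_value=psi_night, extreme_value=1.2 * psi_night)


@dataclass(frozen=True)
class ScenarioInputs:
    """All diurnal inputs for one treatment × condition.

    ``c_pp_mass`` drives the pedicel phloem sucrose concentration as a mass
    fraction (g per g of sap); it is converted to mol g⁻¹ when boundary
    conditions are built.  ``transpiration_per_area`` is in g cm⁻² h⁻¹ and
    is multiplied by the fruit surface area.  ``temperature`` is a constant
    (K) unless an ``hourly_temperature`` series of 24 values is supplied.
    """

    label: str
    treatment: str                      # "30 leaf-to-fruit 1994" etc.
    condition: str                      # "control" | "girdled"
    psi_w_pp: SinusoidDriver
    c_pp_mass: SinusoidDriver
    transpiration_per_area: FullDaySinusoid
    psi_w_fs: SinusoidDriver
    temperature: float = 293.15
    hourly_temperature: tuple | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("control", "girdled"):
            raise ValueError("condition must be 'control' or 'girdled'")
        if not (0 <= self.c_pp_mass.base_value < 1
                and 0 <= self.c_pp_mass.extreme_value < 1):
            raise ValueError("sugar mass fractions must lie in [0, 1)")
        if self.hourly_temperature is not None and len(self.hourly_temperature) != 24:
            raise ValueError("hourly_temperature must have 24 entries")

    def temperature_at(self, hour):
        if self.hourly_temperature is None:
            return self.temperature
        return float(self.hourly_temperature[int(_wrap_hour(hour))])

    def boundary_conditions(self, hour, geom: FruitGeometry) -> BoundaryConditions:
        """Evaluate all drivers at ``hour`` for a fruit of geometry ``geom``."""
        return BoundaryConditions(
            psi_w_pp=self.psi_w_pp(hour),
            C_pp=mass_fraction_to_molar(self.c_pp_mass(hour), M_SUCROSE),
            T_fa=self.transpiration_per_area(hour) * geom.A_f,
            psi_w_fs=self.psi_w_fs(hour),
            temperature=self.temperature_at(hour),
        )


def scenario_preset(label: str, params: ModelParameters | None = None
                    ) -> ScenarioInputs:
    """Build one of the six named scenarios (C30_94, C30_95, C5_95,
    G30_94, G30_95, G5_95).

    The night symplast potential is taken from ``params.psi_fs_night`` when
    a parameter set is given, else from the reference calibration.
    """
    if label not in SCENARIO_LABELS:
        raise KeyError(
            f"unknown scenario {label!r}; choose from {', '.join(SCENARIO_LABELS)}"
        )
    psi_map = (params.psi_fs_night if params is not None
               else REFERENCE_PSI_FS_NIGHT)
    condition = "control" if label.startswith("C") else "girdled"
    ratio = "5" if "5_" in label else "30"
    year = "1994" if label.endswith("94") else "1995"
    return ScenarioInputs(
        label=label,
        treatment=f"{ratio} leaf-to-fruit {year}",
        condition=condition,
        psi_w_pp=_PSI_PP,
        c_pp_mass=_C_PP[ratio],
        transpiration_per_area=_TRANSPIRATION,
        psi_w_fs=symplast_potential_driver(psi_map[label]),
    )


# allometry ---------------------------------------------------------------------

def geometry_from_weight(W: float, dw_fraction: float = DRY_WEIGHT_FRACTION
                         ) -> FruitGeometry:
    """Geometry record from fresh weight (g); dry weight is a fixed
    fraction of W (the daily mean in a one-day simulation)."""
    if W <= 0:
        raise ValueError("fresh weight must be positive")
    D = (W / WEIGHT_COEF) ** (1.0 / WEIGHT_EXP)
    A_f = AREA_COEF * W ** AREA_EXP
    return FruitGeometry(W=W, D=D, A_f=A_f, DW=dw_fraction * W)


def geometry_from_diameter(D: float, dw_fraction: float = DRY_WEIGHT_FRACTION
                           ) -> FruitGeometry:
    """Geometry record from diameter (mm)."""
    if D <= 0:
        raise ValueError("diameter must be positive")
    return geometry_from_weight(WEIGHT_COEF * D ** WEIGHT_EXP, dw_fraction)


def weight_from_diameter(D):
    return WEIGHT_COEF * np.asarray(D, dtype=float) ** WEIGHT_EXP


def diameter_from_weight(W):
    return (np.asarray(W, dtype=float) / WEIGHT_COEF) ** (1.0 / WEIGHT_EXP)


def reference_geometry(params: ModelParameters | None = None,
                       duals: Mapping[str, float] = REFERENCE_DUAL_CONDUCTANCES
                       ) -> FruitGeometry:
    """Geometry of the reference fruit (5 leaf-to-fruit control, 1995).

    The calibration is quoted in two equivalent forms for the three
    area-specific conductivities: k (per cm²) and the bulk conductance
    K = k·A_f at the reference fruit.  The ratios K/k therefore pin the
    reference surface area, and the allometry converts it to a weight —
    the only route to an absolute fruit size, which is not quoted directly.
    """
    params = params or reference_parameters()
    ratios = [duals[name] / getattr(params, name) for name in duals]
    A_f = float(np.mean(ratios))
    W = (A_f / AREA_COEF) ** (1.0 / AREA_EXP)
    return geometry_from_weight(W)


def preset_initial_weight(label: str) -> float:
    """Representative initial fresh weight (g) for a scenario.

    Heavy crop load (5 leaf-to-fruit): the reference-fruit weight derived
    from the dual conductance/conductivity forms (~57 g).  Light crop load
    (30 leaf-to-fruit): 130 g, a representative late stage-III size.
    """
    if label not in SCENARIO_LABELS:
        raise KeyError(f"unknown scenario {label!r}")
    if "5_" in label:
        return reference_geometry().W
    return 130.0


def relative_variation(values, denominator: str = "max") -> float:
    """Diurnal relative-variation functional |(max − min) / denom| with
    ``denom`` the series maximum or minimum."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    vmax, vmin = values.max(), values.min()
    denom = vmax if denominator == "max" else vmin
    if denom == 0:
        raise ZeroDivisionError("relative variation undefined: zero denominator")
    return float(abs((vmax - vmin) / denom))
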