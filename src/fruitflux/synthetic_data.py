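"""Pseudo-observed diurnal fruit series for testing and calibration.

The original gauge recordings (continuous fruit-diameter series from LVDT
displacement transducers) were never deposited, so this module generates
series with the same structure: per-scenario replicate fruits monitored
over whole days, as diameters with additive Gaussian gauge noise.  Control
and girdled series come from the forward model at a chosen "true" parameter
set; detached-fruit series are pure transpirational loss.  Fruit-to-fruit
size heterogeneity is emulated with a lognormal jitter on the initial
weight.

Noise is applied on the diameter scale — the measured quantity — so weight
noise inherits the curvature of the weight–diameter allometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .drivers import (
    diameter_from_weight,
    geometry_from_weight,
    preset_initial_weight,
    scenario_preset,
    weight_from_diameter,
)
from .model_core import ModelParameters, reference_parameters
from .simulate import SimulationConfig, run_day

__all__ = [
    "ObservationSeries",
    "SyntheticConfig",
    "REPLICATION",
    "generate",
    "detached_weight_series",
    "to_relative_weights",
]

#: Replication structure of the field campaigns: scenario → (number of
#: fruits, total days of monitoring).  D* labels are detached fruits.
REPLICATION: Mapping[str, tuple[int, int]] = {
    "C30_94": (3, 31), "G30_94": (5, 29), "D30_94": (7, 29),
    "C30_95": (1, 9), "G30_95": (2, 6), "D30_95": (4, 8),
    "C5_95": (1, 8), "G5_95": (2, 5), "D5_95": (4, 8),
}


@dataclass(frozen=True)
class ObservationSeries:
    """One fruit-day of hourly observations."""

    fruit_id: str
    scenario: str
    condition: str                    # control | girdled | detached
    hours: np.ndarray
    diameter_mm: np.ndarray
    weight_g: np.ndarray

    def __post_init__(self) -> None:
        hours = np.asarray(self.hours, dtype=float)
        if hours.size and np.any(np.diff(hours) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.asarray(self.diameter_mm) <= 0):
            raise ValueError("diameters must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    ``scenarios`` default to all nine labels with the study's replication
    counts; ``noise_sd_mm`` is the gauge noise on diameter; ``w0_cv`` the
    coefficient of variation of the lognormal initial-weight jitter.
    """

    params: ModelParameters = field(default_factory=reference_parameters)
    scenarios: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(REPLICATION))
    noise_sd_mm: float = 0.02
    w0_cv: float = 0.10
    reference_hour: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0 or self.w0_cv < 0:
            raise ValueError("noise scales must be nonnegative")
        for label, (n_fruits, n_days) in self.scenarios.items():
            if n_fruits < 1 or n_days < 1:
                raise ValueError(f"replication counts for {label} must be >= 1")
            if n_days < n_fruits:
                raise ValueError(
                    f"{label}: total monitored days ({n_days}) cannot be "
                    f"fewer than the number of fruits ({n_fruits})")


def detached_weight_series(label: str, W0: float, hours: np.ndarray) -> np.ndarray:
    """Weight of a detached (pedicel-severed) fruit: no vascular inflow, so
    the fruit only loses the transpiration integral T_fa = rate·A_f."""
    scenario = scenario_preset("C" + label[1:])   # detached shares the drivers
    geom = geometry_from_weight(W0)
    loss = scenario.transpiration_per_area(hours) * geom.A_f
    dt = float(hours[1] - hours[0]) if len(hours) > 1 else 1.0
    return W0 - np.concatenate([[0.0], np.cumsum(loss) * dt])[:-1]


def _base_label(label: str) -> str:
    condition = {"C": "control", "G": "girdled", "D": "detached"}[label[0]]
    return condition


def generate(config: SyntheticConfig) -> list[ObservationSeries]:
    """Generate all configured scenario series; deterministic in the seed.

    For control/girdled fruits each fruit-day is a forward simulation at
    the true parameters from a jittered initial weight, converted to
    diameters, plus gauge noise.  With ``noise_sd_mm = 0`` and
    ``w0_cv = 0`` the series reproduce the forward model exactly.
    """
    rng = np.random.default_rng(config.seed)
    hours = np.arange(24.0)
    out: list[ObservationSeries] = []
    sigma = np.sqrt(np.log1p(config.w0_cv ** 2))   # lognormal, unit median

    for label in sorted(config.scenarios):
        n_fruits, total_days = config.scenarios[label]
        condition = _base_label(label)
        w_base = preset_initial_weight(label if condition != "detached"
                                       else "C" + label[1:])
        days_each = np.full(n_fruits, total_days // n_fruits, dtype=int)
        days_each[: total_days % n_fruits] += 1
        for f in range(n_fruits):
            w0 = w_base * rng.lognormal(mean=0.0, sigma=sigma) if sigma else w_base
            if condition == "detached":
                weights = detached_weight_series(label, w0, hours)
            else:
                scenario = scenario_preset(label, config.params)
                result = run_day(SimulationConfig(
                    scenario=scenario, params=config.params, W0=w0,
                    reference_hour=config.reference_hour))
                weights = result.weight
            diam_clean = diameter_from_weight(weights)
            for day in range(days_each[f]):
                noise = rng.normal(0.0, config.noise_sd_mm, size=hours.size) \
                    if config.noise_sd_mm else np.zeros(hours.size)
                diam = diam_clean + noise
                out.append(ObservationSeries(
                    fruit_id=f"{label}_f{f + 1}_d{day + 1}",
                    scenario=label,
                    condition=condition,
                    hours=hours.copy(),
                    diameter_mm=diam,
                    weight_g=weight_from_diameter(diam),
                ))
    return out


def to_relative_weights(series: ObservationSeries | np.ndarray,
                        reference_hour: float = 9.0,
                        hours: np.ndarray | None = None) -> np.ndarray:
    """Weight series relative to the reference hour:
    (W_h − W_ref) / W_ref, exactly zero at the reference hour."""
    if isinstance(series, ObservationSeries):
        weights = np.asarray(series.weight_g, dtype=float)
        hours = np.asarray(series.hours, dtype=float)
    else:
        weights = np.asarray(series, dtype=float)
        if hours is None:
            hours = np.arange(len(weights), dtype=float)
    idx = np.flatnonzero(np.isclose(np.mod(hours, 24.0), reference_hour % 24.0))
    if idx.size == 0:
        raise ValueError(f"reference hour {reference_hour:g} not present")
    w_ref = weights[idx[0]]
    return (weights - w_ref) / w_ref
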