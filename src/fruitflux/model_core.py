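"""Steady-state water and sugar transport in the pedicel–fruit system.

The system is a network of five compartments: pedicel xylem (px) and phloem
(pp), fruit xylem (fx) and phloem (fp), fruit apoplast (fa), plus the fruit
symplast (fs) as a boundary compartment.  Two equilibrium hypotheses close
the network: the xylem and phloem share the same water potential, and the
(solute-free) xylem pressure potential equals the xylem water potential.

At each hour the vascular compartments are assumed to be at steady state,
so mass conservation of water and sugar yields a 4×4 linear system in the
unknowns (Ψp_fp, Ψp_fa, C_fp, C_fa): fruit phloem pressure potential, fruit
apoplast pressure potential, fruit phloem sucrose concentration, and fruit
apoplast hexose concentration.  All other potentials and the nine flows are
derived from the solution.

Sign convention: every pairwise flow U_a_b is positive in the a→b direction
(toward the fruit / inner compartment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "ModelParameters",
    "BoundaryConditions",
    "FruitGeometry",
    "SteadyState",
    "NonPhysicalSolutionWarning",
    "SingularSystemError",
    "REFERENCE_PSI_FS_NIGHT",
    "REFERENCE_DUAL_CONDUCTANCES",
    "reference_parameters",
    "osmotic_potential",
    "mass_fraction_to_molar",
    "water_flow_pressure_driven",
    "water_flow_membrane",
    "sugar_mass_flow",
    "sugar_phloem_to_apoplast",
    "sugar_uptake_symplast",
    "assemble_control_system",
    "solve_control",
    "solve_girdled",
    "conservation_residuals",
]

#: Scenario labels: C/G = control (intact) / girdled pedicel; 30/5 =
#: leaf-to-fruit ratio; 94/95 = year of the field campaign.
SCENARIO_LABELS = ("C30_94", "C30_95", "C5_95", "G30_94", "G30_95", "G5_95")

#: Calibrated night-time fruit symplast water potential per scenario, MPa.
REFERENCE_PSI_FS_NIGHT: Mapping[str, float] = MappingProxyType(
    {
        "C30_94": -1.7,
        "C30_95": -1.7,
        "C5_95": -1.3,
        "G30_94": -0.89,
        "G30_95": -1.1,
        "G5_95": -0.91,
    }
)

#: Bulk-conductance duals (g h⁻¹ MPa⁻¹) of the three area-specific
#: conductivities, quoted at the reference fruit (5 leaf-to-fruit control,
#: 1995).  The k/K pairs pin the reference fruit surface area.
REFERENCE_DUAL_CONDUCTANCES: Mapping[str, float] = MappingProxyType(
    {"k_fx_fa": 7.4e-1, "k_fp_fa": 7.6e-2, "k_fa_fs": 6.4e-1}
)


class NonPhysicalSolutionWarning(UserWarning):
    """A solved steady state has a negative sugar concentration."""


class SingularSystemError(np.linalg.LinAlgError):
    """The assembled steady-state system is singular or ill-conditioned."""


@dataclass(frozen=True)
class ModelParameters:
    """Biophysical parameters of the transport network.

    Conductances ``K_*`` are bulk (g h⁻¹ MPa⁻¹); conductivities ``k_*`` are
    per unit fruit surface area (g h⁻¹ MPa⁻¹ cm⁻²).  ``v_fp_fa`` is the
    phloem→apoplast sugar transport coefficient (g h⁻¹ cm⁻², lumping
    diffusion and active efflux); ``v_fa_fs`` (h⁻¹) is the *net* symplastic
    uptake coefficient, already discounted for respiration.
    ``psi_fs_night`` maps scenario labels to the night-time symplast water
    potential (MPa), the only per-scenario parameter.
    """

    K_px_fx: float
    K_pp_fp: float
    k_fx_fa: float
    k_fp_fa: float
    k_fa_fs: float
    v_fp_fa: float
    v_fa_fs: float
    psi_fs_night: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_PSI_FS_NIGHT)
    )
    constants: PhysicalConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        for name in ("K_px_fx", "K_pp_fp", "k_fx_fa", "k_fp_fa", "k_fa_fs",
                     "v_fp_fa", "v_fa_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for label, psi in self.psi_fs_night.items():
            if psi >= 0:
                raise ValueError(
                    f"psi_fs_night[{label!r}] must be negative (got {psi})"
                )

    def with_psi_fs(self, mapping: Mapping[str, float]) -> "ModelParameters":
        return replace(self, psi_fs_night=dict(mapping))


def reference_parameters() -> ModelParameters:
    """Calibrated parameter set for late stage-III 'Suncrest' peach."""
    return ModelParameters(
        K_px_fx=9.1e-1,
        K_pp_fp=3.3,
        k_fx_fa=1.1e-2,
        k_fp_fa=1.1e-3,
        k_fa_fs=9.1e-3,
        v_fp_fa=5.0e-4,
        v_fa_fs=3.6e-2,
    )


@dataclass(frozen=True)
class FruitGeometry:
    """Fresh weight W (g), diameter D (mm), surface area A_f (cm²) and dry
    weight DW (g), linked by the 'Suncrest' allometries (see drivers)."""

    W: float
    D: float
    A_f: float
    DW: float

    def __post_init__(self) -> None:
        for name in ("W", "D", "A_f", "DW"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """External state of the system for one hour.

    psi_w_pp : pedicel water potential, MPa (shared by pedicel xylem and
        phloem under the equal-water-potential hypothesis).
    C_pp : pedicel phloem sucrose concentration, mol g⁻¹.
    T_fa : fruit transpiration, g h⁻¹.
    psi_w_fs : fruit symplast water potential, MPa.
    temperature : K.
    """

    psi_w_pp: float
    C_pp: float
    T_fa: float
    psi_w_fs: float
    temperature: float = 293.15
    constants: PhysicalConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.C_pp < 0:
            raise ValueError("C_pp must be nonnegative")
        if self.T_fa < 0:
            raise ValueError("T_fa must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def psi_p_px(self) -> float:
        """Pedicel xylem pressure potential: solute-free, so equal to the
        pedicel water potential."""
        return self.psi_w_pp

    @property
    def psi_p_pp(self) -> float:
        """Pedicel phloem pressure potential: offsets the osmotic pull of
        the phloem sap, Ψp = Ψw + R·T·C."""
        c = self.constants
        return self.psi_w_pp + c.R * self.temperature * self.C_pp


@dataclass(frozen=True)
class SteadyState:
    """Solved steady state for one hour: the four unknowns, derived
    potentials, the six pairwise water flows and three sugar flows."""

    # unknowns
    psi_p_fp: float
    psi_p_fa: float
    C_fp: float
    C_fa: float
    # derived potentials
    psi_w_fp: float  # == psi_w_fx == psi_p_fx (xylem solute-free)
    psi_w_fa: float
    # water flows, g h⁻¹ (positive toward the fruit interior)
    U_px_fx: float
    U_pp_fp: float
    U_fx_fa: float
    U_fp_fa: float
    U_fa_fs: float
    U_fx_fp: float  # lateral xylem→phloem transfer
    # sugar flows, g h⁻¹
    S_pp_fp: float
    S_fp_fa: float
    S_fa_fs: float
    nonphysical: bool = False

    @property
    def psi_p_fx(self) -> float:
        return self.psi_w_fp


# ---------------------------------------------------------------------------
# elementary flow laws
# ---------------------------------------------------------------------------

def osmotic_potential(temperature, C, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Osmotic potential Ψπ = −R·T·C (MPa) of a solution of molar (per gram)
    concentration ``C`` at temperature ``temperature`` (K)."""
    temperature = np.asarray(temperature, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(temperature <= 0):
        raise ValueError("temperature must be positive")
    if np.any(C < 0):
        raise ValueError("concentration must be nonnegative")
    out = -constants.R * temperature * C
    return out.item() if out.ndim == 0 else out


def mass_fraction_to_molar(c_mass, molar_mass):
    """Convert a sap concentration from mass fraction (g per g of solution)
    to mol per g of solution."""
    c_mass = np.asarray(c_mass, dtype=float)
    if np.any(c_mass < 0) or np.any(c_mass >= 1):
        raise ValueError("mass fraction must lie in [0, 1)")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    out = c_mass / molar_mass
    return out.item() if out.ndim == 0 else out


def water_flow_pressure_driven(K, psi_p_upstream, psi_p_downstream):
    """Bulk flow (g h⁻¹) through a conduit of conductance ``K``
    (g h⁻¹ MPa⁻¹), driven by the pressure-potential difference; positive
    toward the downstream compartment."""
    if K <= 0:
        raise ValueError("conductance K must be strictly positive")
    return K * (np.asarray(psi_p_upstream, float) - np.asarray(psi_p_downstream, float))


def water_flow_membrane(k, A_f, psi_w_upstream, psi_w_downstream):
    """Trans-membrane flow (g h⁻¹) across an exchange surface proportional
    to the fruit area ``A_f`` (cm²), driven by the *water*-potential
    difference (membranes are semi-permeable, so solutes count)."""
    if k <= 0:
        raise ValueError("conductivity k must be strictly positive")
    if A_f <= 0:
        raise ValueError("A_f must be strictly positive")
    return k * A_f * (np.asarray(psi_w_upstream, float) - np.asarray(psi_w_downstream, float))


def sugar_mass_flow(C_pp, U_pp_fp, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Sucrose carried by Münch mass flow from pedicel to fruit phloem,
    S = M_S·C_pp·U (g h⁻¹); the sign follows the water flow."""
    if np.any(np.asarray(C_pp, float) < 0):
        raise ValueError("C_pp must be nonnegative")
    return constants.M_S * np.asarray(C_pp, float) * np.asarray(U_pp_fp, float)


def sugar_phloem_to_apoplast(C_fp, A_f, v_fp_fa,
                             constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Sucrose efflux from fruit phloem to apoplast (diffusion + active
    transport lumped): S = M_S·v·A_f·C_fp (g h⁻¹), nonnegative."""
    if np.any(np.asarray(C_fp, float) < 0):
        raise ValueError("C_fp must be nonnegative")
    return constants.M_S * v_fp_fa * A_f * np.asarray(C_fp, float)


def sugar_uptake_symplast(C_fa, DW, v_fa_fs,
                          constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Net hexose uptake by the symplast, S = M_H·v·C_fa·DW (g h⁻¹); the
    coefficient is net of respiration losses."""
    if np.any(np.asarray(C_fa, float) < 0):
        raise ValueError("C_fa must be nonnegative")
    if DW <= 0:
        raise ValueError("DW must be strictly positive")
    return constants.M_H * v_fa_fs * np.asarray(C_fa, float) * DW


# ---------------------------------------------------------------------------
# linear system assembly and solution
# ---------------------------------------------------------------------------
# Unknown ordering (fixed): x = [psi_p_fp, psi_p_fa, C_fp, C_fa].
# Row ordering (fixed): pedicel↔fruit water conservation; fruit water
# conservation incl. transpiration; phloem sugar conservation; fruit sugar
# conservation.

def _assemble_arrays(psi_w_pp, C_pp, T_fa, psi_w_fs, temperature,
                     params: ModelParameters, geom: FruitGeometry):
    """Vectorized assembly: inputs broadcast to shape ``s``; returns
    (A, b) with shapes ``s + (4, 4)`` and ``s + (4,)``."""
    c = params.constants
    psi_w_pp, C_pp, T_fa, psi_w_fs, temperature = np.broadcast_arrays(
        *(np.asarray(v, dtype=float)
          for v in (psi_w_pp, C_pp, T_fa, psi_w_fs, temperature))
    )
    RT = c.R * temperature
    Af = geom.A_f
    Kpx, Kpp = params.K_px_fx, params.K_pp_fp
    kxa, kpa, kas = params.k_fx_fa * Af, params.k_fp_fa * Af, params.k_fa_fs * Af

    shape = psi_w_pp.shape
    A = np.zeros(shape + (4, 4))
    b = np.zeros(shape + (4,))

    # water conservation pedicel→fruit: U_px_fx + U_pp_fp − U_fx_fa − U_fp_fa = 0
    A[..., 0, 0] = -(Kpx + Kpp + kxa + kpa)
    A[..., 0, 1] = kxa + kpa
    A[..., 0, 2] = RT * (Kpx + kxa + kpa)
    A[..., 0, 3] = -RT * kpa
    b[..., 0] = -(Kpx * psi_w_pp + Kpp * (psi_w_pp + RT * C_pp))

    # fruit water conservation: U_fx_fa + U_fp_fa − U_fa_fs − T_fa = 0
    A[..., 1, 0] = kxa + kpa
    A[..., 1, 1] = -(kxa + kpa + kas)
    A[..., 1, 2] = -RT * (kxa + kpa)
    A[..., 1, 3] = RT * (kpa + kas)
    b[..., 1] = T_fa - kas * psi_w_fs

    # phloem sugar conservation: S_pp_fp − S_fp_fa = 0
    A[..., 2, 0] = -c.M_S * C_pp * Kpp
    A[..., 2, 2] = -c.M_S * params.v_fp_fa * Af
    b[..., 2] = -c.M_S * C_pp * Kpp * (psi_w_pp + RT * C_pp)

    # fruit sugar conservation: S_fp_fa − S_fa_fs = 0
    A[..., 3, 2] = c.M_S * params.v_fp_fa * Af
    A[..., 3, 3] = -c.M_H * params.v_fa_fs * geom.DW

    return A, b


def assemble_control_system(bc: BoundaryConditions, params: ModelParameters,
                            geom: FruitGeometry):
    """Assemble the 4×4 steady-state system ``A x = b`` for the intact
    (control) fruit.  Unknown ordering: (Ψp_fp, Ψp_fa, C_fp, C_fa)."""
    A, b = _assemble_arrays(bc.psi_w_pp, bc.C_pp, bc.T_fa, bc.psi_w_fs,
                            bc.temperature, params, geom)
    return A, b


def _solve_linear(A, b):
    try:
        # keep an explicit trailing vector axis so stacked systems solve
        # as vectors regardless of broadcasting heuristics
        x = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(A)
        raise SingularSystemError(
            f"steady-state system is singular (condition number {cond:.3e})"
        ) from exc
    return x


def _derive_state(x, psi_w_pp, C_pp, T_fa, psi_w_fs, temperature,
                  params: ModelParameters, geom: FruitGeometry):
    """Derived potentials and flows from a solution array x[..., 4]."""
    c = params.constants
    RT = c.R * np.asarray(temperature, dtype=float)
    Af = geom.A_f
    p_fp, p_fa, C_fp, C_fa = (x[..., i] for i in range(4))
    psi_w_fp = p_fp - RT * C_fp       # == psi_w_fx == psi_p_fx
    psi_w_fa = p_fa - RT * C_fa
    psi_p_pp = psi_w_pp + RT * C_pp

    U_px_fx = params.K_px_fx * (psi_w_pp - psi_w_fp)
    U_pp_fp = params.K_pp_fp * (psi_p_pp - p_fp)
    U_fx_fa = params.k_fx_fa * Af * (psi_w_fp - p_fa)
    U_fp_fa = params.k_fp_fa * Af * (psi_w_fp - psi_w_fa)
    U_fa_fs = params.k_fa_fs * Af * (psi_w_fa - psi_w_fs)
    U_fx_fp = U_px_fx - U_fx_fa

    S_pp_fp = c.M_S * C_pp * U_pp_fp
    S_fp_fa = c.M_S * params.v_fp_fa * Af * C_fp
    S_fa_fs = c.M_H * params.v_fa_fs * C_fa * geom.DW
    return dict(
        psi_p_fp=p_fp, psi_p_fa=p_fa, C_fp=C_fp, C_fa=C_fa,
        psi_w_fp=psi_w_fp, psi_w_fa=psi_w_fa,
        U_px_fx=U_px_fx, U_pp_fp=U_pp_fp, U_fx_fa=U_fx_fa,
        U_fp_fa=U_fp_fa, U_fa_fs=U_fa_fs, U_fx_fp=U_fx_fp,
        S_pp_fp=S_pp_fp, S_fp_fa=S_fp_fa, S_fa_fs=S_fa_fs,
    )


def _state_from_fields(fields: dict, idx=None) -> SteadyState:
    vals = {k: (float(v[idx]) if idx is not None else float(v))
            for k, v in fields.items()}
    nonphys = vals["C_fp"] < 0 or vals["C_fa"] < 0
    return SteadyState(nonphysical=bool(nonphys), **vals)


def solve_control(bc: BoundaryConditions, params: ModelParameters,
                  geom: FruitGeometry) -> SteadyState:
    """Solve the control (intact fruit) steady state for one hour.

    Negative solved concentrations are physically impossible and flag the
    parameter set as inconsistent with the inputs; they are reported via a
    :class:`NonPhysicalSolutionWarning` rather than clipped, so calibration
    can penalize them.
    """
    A, b = assemble_control_system(bc, params, geom)
    x = _solve_linear(A, b)
    fields = _derive_state(x, bc.psi_w_pp, bc.C_pp, bc.T_fa, bc.psi_w_fs,
                           bc.temperature, params, geom)
    state = _state_from_fields(fields)
    if state.nonphysical:
        warnings.warn(
            "steady state solved with a negative sugar concentration "
            f"(C_fp={state.C_fp:.3e}, C_fa={state.C_fa:.3e})",
            NonPhysicalSolutionWarning,
            stacklevel=2,
        )
    return state


def _solve_girdled_arrays(psi_w_pp, T_fa, psi_w_fs, params: ModelParameters,
                          geom: FruitGeometry):
    """Reduced water-only system of the girdled fruit.

    Girdling severs the phloem, so U_pp_fp = U_fp_fa = 0 and every sugar
    flow vanishes; the remaining unknowns are the fruit xylem and apoplast
    pressure potentials with conservation U_px_fx = U_fx_fa = U_fa_fs + T_fa.
    """
    psi_w_pp, T_fa, psi_w_fs = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (psi_w_pp, T_fa, psi_w_fs)))
    Af = geom.A_f
    Kpx = params.K_px_fx
    kxa, kas = params.k_fx_fa * Af, params.k_fa_fs * Af

    shape = psi_w_pp.shape
    A = np.zeros(shape + (2, 2))
    b = np.zeros(shape + (2,))
    # U_px_fx − U_fx_fa = 0
    A[..., 0, 0] = -(Kpx + kxa)
    A[..., 0, 1] = kxa
    b[..., 0] = -Kpx * psi_w_pp
    # U_fx_fa − U_fa_fs − T_fa = 0
    A[..., 1, 0] = kxa
    A[..., 1, 1] = -(kxa + kas)
    b[..., 1] = T_fa - kas * psi_w_fs

    x = _solve_linear(A, b)
    p_fx, p_fa = x[..., 0], x[..., 1]
    U_px_fx = Kpx * (psi_w_pp - p_fx)
    U_fx_fa = kxa * (p_fx - p_fa)
    U_fa_fs = kas * (p_fa - psi_w_fs)
    zero = np.zeros_like(p_fx)
    return dict(
        psi_p_fp=p_fx, psi_p_fa=p_fa, C_fp=zero, C_fa=zero,
        psi_w_fp=p_fx, psi_w_fa=p_fa,
        U_px_fx=U_px_fx, U_pp_fp=zero, U_fx_fa=U_fx_fa,
        U_fp_fa=zero, U_fa_fs=U_fa_fs, U_fx_fp=U_px_fx - U_fx_fa,
        S_pp_fp=zero, S_fp_fa=zero, S_fa_fs=zero,
    )


def solve_girdled(bc: BoundaryConditions, params: ModelParameters,
                  geom: FruitGeometry) -> SteadyState:
    """Solve the girdled-pedicel steady state (no phloem, no sugar flows).

    By convention the fruit phloem of a girdled fruit is reported at the
    xylem pressure with zero sugar, which keeps the
    :class:`SteadyState` record shape identical to the control case.
    """
    fields = _solve_girdled_arrays(bc.psi_w_pp, bc.T_fa, bc.psi_w_fs,
                                   params, geom)
    return _state_from_fields(fields)


def conservation_residuals(state: SteadyState, bc: BoundaryConditions,
                           params: ModelParameters, geom: FruitGeometry):
    """Residuals of the four conservation laws at a solved state:
    (pedicel↔fruit water, fruit water incl. transpiration, phloem sugar,
    fruit sugar), all in g h⁻¹."""
    r_water_vasc = state.U_px_fx + state.U_pp_fp - state.U_fx_fa - state.U_fp_fa
    r_water_fruit = state.U_fx_fa + state.U_fp_fa - state.U_fa_fs - bc.T_fa
    r_sugar_phloem = state.S_pp_fp - state.S_fp_fa
    r_sugar_fruit = state.S_fp_fa - state.S_fa_fs
    return r_water_vasc, r_water_fruit, r_sugar_phloem, r_sugar_fruit
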