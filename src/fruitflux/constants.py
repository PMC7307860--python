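"""Physical constants used throughout the model.

The model works in a gram-based unit system: masses in g, flows in g h⁻¹,
potentials in MPa, areas in cm², concentrations in mol per g of solution.
With sap density taken as 1 g cm⁻³, the gas constant
R = 8.314 MPa cm³ mol⁻¹ K⁻¹ is numerically 8.314 in these units, so the
osmotic term R·T·C (MPa) comes out directly from a mol g⁻¹ concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant, MPa g mol⁻¹ K⁻¹ under the unit-density convention.
R_GAS = 8.314

#: Sucrose molar mass, g mol⁻¹ (the phloem-transported sugar).
M_SUCROSE = 342.30

#: Hexose molar mass, g mol⁻¹ (apoplastic sucrose is invertase-split into
#: glucose + fructose before symplastic uptake).
M_HEXOSE = 180.16


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants, overridable for sensitivity studies."""

    R: float = R_GAS
    M_S: float = M_SUCROSE
    M_H: float = M_HEXOSE

    def __post_init__(self) -> None:
        if self.R <= 0 or self.M_S <= 0 or self.M_H <= 0:
            raise ValueError("physical constants must be strictly positive")
        if self.M_S <= self.M_H:
            raise ValueError("sucrose molar mass must exceed hexose molar mass")


DEFAULT_CONSTANTS = PhysicalConstants()
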