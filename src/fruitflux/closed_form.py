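"""Closed-form solution of the control steady-state system.

The 4×4 linear system is solved once symbolically (sympy, Gaussian
elimination over the rational function field) and the resulting algebraic
expressions are lambdified.  This is an independent solution route from the
numeric LU factorization in :mod:`fruitflux.model_core` and is used as a
cross-check oracle in the test suite; it is also handy for fast repeated
evaluation and for inspecting parameter sensitivities analytically.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .constants import PhysicalConstants, DEFAULT_CONSTANTS
from .model_core import FruitGeometry, ModelParameters, BoundaryConditions

__all__ = ["symbolic_solution", "solve_control_closed_form"]

_ARG_NAMES = (
    "psi_pp", "C_pp", "T_fa", "psi_fs", "RT",
    "K_px", "K_pp", "k_xa", "k_pa", "k_as", "v_pa", "v_as",
    "A_f", "DW", "M_S", "M_H",
)


@lru_cache(maxsize=1)
def symbolic_solution():
    """Symbolic expressions for (Ψp_fp, Ψp_fa, C_fp, C_fa).

    Returns a dict mapping unknown names to sympy expressions in the
    symbols named in ``_ARG_NAMES``.
    """
    (psi_pp, C_pp, T_fa, psi_fs, RT,
     K_px, K_pp, k_xa, k_pa, k_as, v_pa, v_as,
     A_f, DW, M_S, M_H) = syms = sp.symbols(" ".join(_ARG_NAMES))

    p_fp, p_fa, C_fp, C_fa = unknowns = sp.symbols("p_fp p_fa C_fp C_fa")

    psi_w_fp = p_fp - RT * C_fp          # fruit phloem = fruit xylem water potential
    psi_w_fa = p_fa - RT * C_fa
    psi_p_pp = psi_pp + RT * C_pp

    U_px = K_px * (psi_pp - psi_w_fp)
    U_pp = K_pp * (psi_p_pp - p_fp)
    U_xa = k_xa * A_f * (psi_w_fp - p_fa)
    U_pa = k_pa * A_f * (psi_w_fp - psi_w_fa)
    U_as = k_as * A_f * (psi_w_fa - psi_fs)

    S_pp = M_S * C_pp * U_pp
    S_pa = M_S * v_pa * A_f * C_fp
    S_as = M_H * v_as * C_fa * DW

    equations = [
        sp.Eq(U_px + U_pp, U_xa + U_pa),
        sp.Eq(U_xa + U_pa, U_as + T_fa),
        sp.Eq(S_pp, S_pa),
        sp.Eq(S_pa, S_as),
    ]
    (solution,) = sp.linsolve(equations, unknowns)
    exprs = {
        "psi_p_fp": sp.simplify(solution[0]),
        "psi_p_fa": sp.simplify(solution[1]),
        "C_fp": sp.simplify(solution[2]),
        "C_fa": sp.simplify(solution[3]),
    }
    return exprs, syms


@lru_cache(maxsize=1)
def _lambdified():
    exprs, syms = symbolic_solution()
    return {name: sp.lambdify(syms, expr, modules="numpy")
            for name, expr in exprs.items()}


def solve_control_closed_form(bc: BoundaryConditions, params: ModelParameters,
                              geom: FruitGeometry) -> dict:
    """Evaluate the closed-form control solution at the given inputs.

    Returns the four unknowns as floats (or arrays if the boundary fields
    broadcast).  Derived flows can be recovered with the flow laws of
    :mod:`fruitflux.model_core`.
    """
    c: PhysicalConstants = params.constants or DEFAULT_CONSTANTS
    funcs = _lambdified()
    args = dict(
        psi_pp=bc.psi_w_pp, C_pp=bc.C_pp, T_fa=bc.T_fa, psi_fs=bc.psi_w_fs,
        RT=c.R * bc.temperature,
        K_px=params.K_px_fx, K_pp=params.K_pp_fp,
        k_xa=params.k_fx_fa, k_pa=params.k_fp_fa, k_as=params.k_fa_fs,
        v_pa=params.v_fp_fa, v_as=params.v_fa_fs,
        A_f=geom.A_f, DW=geom.DW, M_S=c.M_S, M_H=c.M_H,
    )
    ordered = [args[name] for name in _ARG_NAMES]
    return {name: float(np.asarray(f(*ordered))) for name, f in funcs.items()}
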