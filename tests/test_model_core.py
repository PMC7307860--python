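"""Flow laws, system assembly and the two steady-state solvers."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fruitflux as ff
from fruitflux.constants import M_SUCROSE, M_HEXOSE, R_GAS
from fruitflux.model_core import (
    sugar_mass_flow,
    sugar_phloem_to_apoplast,
    sugar_uptake_symplast,
    water_flow_membrane,
    water_flow_pressure_driven,
)

finite = st.floats(allow_nan=False, allow_infinity=False)


class TestOsmoticPotential:
    def test_zero_solute(self):
        assert ff.osmotic_potential(293.15, 0.0) == 0.0

    def test_sucrose_sap(self):
        # 0.12 g/g sucrose sap at 20 °C
        c = ff.mass_fraction_to_molar(0.12, M_SUCROSE)
        expected = -R_GAS * 293.15 * 0.12 / M_SUCROSE
        assert ff.osmotic_potential(293.15, c) == pytest.approx(expected, rel=1e-12)
        assert ff.osmotic_potential(293.15, c) == pytest.approx(-0.8545, abs=5e-4)

    @given(st.floats(1e-6, 1e-3), st.floats(250.0, 320.0))
    def test_linearity_in_concentration(self, c, temp):
        assert ff.osmotic_potential(temp, 2 * c) == pytest.approx(
            2 * ff.osmotic_potential(temp, c), rel=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            ff.osmotic_potential(293.15, -1e-6)
        with pytest.raises(ValueError):
            ff.osmotic_potential(0.0, 1e-4)

    def test_water_potential_decomposition(self):
        # Ψw = Ψp + Ψπ with Ψπ negative
        psi_p, c = 0.3, 2e-4
        psi_pi = ff.osmotic_potential(293.15, c)
        assert psi_pi < 0
        assert psi_p + psi_pi == pytest.approx(psi_p - R_GAS * 293.15 * c)


class TestMassFractionConversion:
    @pytest.mark.parametrize(
        "c_mass, expected",
        [(0.0, 0.0), (0.28, 8.180e-4), (0.08, 2.337e-4)],
    )
    def test_examples(self, c_mass, expected):
        assert ff.mass_fraction_to_molar(c_mass, M_SUCROSE) == pytest.approx(
            expected, rel=1e-3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ff.mass_fraction_to_molar(1.0, M_SUCROSE)
        with pytest.raises(ValueError):
            ff.mass_fraction_to_molar(-0.1, M_SUCROSE)


class TestFlowLaws:
    def test_no_gradient_no_flow(self):
        assert water_flow_pressure_driven(3.3, -0.5, -0.5) == 0.0
        assert water_flow_membrane(1.1e-3, 96.3, -0.7, -0.7) == 0.0

    def test_pressure_driven_magnitude(self):
        assert water_flow_pressure_driven(3.3, 0.0, -0.1) == pytest.approx(0.33)

    def test_membrane_magnitude(self):
        A_f = ff.geometry_from_weight(100.0).A_f
        assert water_flow_membrane(1.1e-3, A_f, 0.0, -0.5) == pytest.approx(
            1.1e-3 * A_f * 0.5, rel=1e-12)
        assert water_flow_membrane(1.1e-3, A_f, 0.0, -0.5) == pytest.approx(
            0.0530, abs=5e-4)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_antisymmetry(self, a, b):
        assert water_flow_pressure_driven(0.91, a, b) == pytest.approx(
            -water_flow_pressure_driven(0.91, b, a), abs=1e-12)
        assert water_flow_membrane(9.1e-3, 70.0, a, b) == pytest.approx(
            -water_flow_membrane(9.1e-3, 70.0, b, a), abs=1e-12)

    @given(st.floats(10.0, 300.0))
    def test_membrane_flow_scales_with_area(self, area):
        base = water_flow_membrane(1.1e-3, 1.0, -0.2, -0.7)
        assert water_flow_membrane(1.1e-3, area, -0.2, -0.7) == pytest.approx(
            area * base, rel=1e-12)

    def test_rejects_nonpositive_conductance(self):
        with pytest.raises(ValueError):
            water_flow_pressure_driven(0.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            water_flow_membrane(1e-3, 0.0, 0.0, -1.0)


class TestSugarFlows:
    def test_mass_flow_examples(self):
        assert sugar_mass_flow(3.5e-4, 0.0) == 0.0
        assert sugar_mass_flow(0.0, 1.7) == 0.0
        assert sugar_mass_flow(3.506e-4, 0.2) == pytest.approx(0.0240, abs=1e-4)

    def test_mass_flow_sign_follows_water(self):
        assert sugar_mass_flow(3.5e-4, -0.2) < 0

    def test_phloem_efflux(self):
        assert sugar_phloem_to_apoplast(0.0, 96.3, 5.0e-4) == 0.0
        assert sugar_phloem_to_apoplast(5e-4, 96.3, 5.0e-4) == pytest.approx(
            8.24e-3, rel=2e-3)
        assert sugar_phloem_to_apoplast(5e-4, 2 * 96.3, 5.0e-4) == pytest.approx(
            2 * sugar_phloem_to_apoplast(5e-4, 96.3, 5.0e-4), rel=1e-12)

    def test_symplast_uptake(self):
        assert sugar_uptake_symplast(0.0, 10.0, 3.6e-2) == 0.0
        assert sugar_uptake_symplast(1.266e-4, 10.0, 3.6e-2) == pytest.approx(
            8.21e-3, rel=2e-3)
        assert sugar_uptake_symplast(1.266e-4, 20.0, 3.6e-2) == pytest.approx(
            2 * sugar_uptake_symplast(1.266e-4, 10.0, 3.6e-2), rel=1e-12)


def _independent_conservation_residuals(x, bc, params, geom):
    """The four conservation laws written directly with the elementary flow
    laws — an assembly-independent route used to check the matrix."""
    c = params.constants
    RT = c.R * bc.temperature
    p_fp, p_fa, C_fp, C_fa = x
    psi_w_fp = p_fp - RT * C_fp
    psi_w_fa = p_fa - RT * C_fa
    U_px = water_flow_pressure_driven(params.K_px_fx, bc.psi_p_px, psi_w_fp)
    U_pp = water_flow_pressure_driven(params.K_pp_fp, bc.psi_p_pp, p_fp)
    U_xa = water_flow_pressure_driven(params.k_fx_fa * geom.A_f, psi_w_fp, p_fa)
    U_pa = water_flow_membrane(params.k_fp_fa, geom.A_f, psi_w_fp, psi_w_fa)
    U_as = water_flow_membrane(params.k_fa_fs, geom.A_f, psi_w_fa, bc.psi_w_fs)
    S_pp = sugar_mass_flow(bc.C_pp, U_pp)
    S_pa = sugar_phloem_to_apoplast(max(C_fp, 0.0), geom.A_f, params.v_fp_fa) \
        if C_fp >= 0 else c.M_S * params.v_fp_fa * geom.A_f * C_fp
    S_as = c.M_H * params.v_fa_fs * C_fa * geom.DW
    return np.array([
        U_px + U_pp - U_xa - U_pa,
        U_xa + U_pa - U_as - bc.T_fa,
        S_pp - S_pa,
        S_pa - S_as,
    ])


class TestControlSolver:
    def test_quiescent_equilibrium(self, params):
        geom = ff.geometry_from_weight(57.0)
        bc = ff.BoundaryConditions(psi_w_pp=-0.6, C_pp=0.0, T_fa=0.0,
                                   psi_w_fs=-0.6)
        state = ff.solve_control(bc, params, geom)
        assert state.psi_p_fp == pytest.approx(-0.6, abs=1e-12)
        assert state.psi_p_fa == pytest.approx(-0.6, abs=1e-12)
        assert state.C_fp == pytest.approx(0.0, abs=1e-15)
        assert state.C_fa == pytest.approx(0.0, abs=1e-15)
        for name in ("U_px_fx", "U_pp_fp", "U_fx_fa", "U_fp_fa", "U_fa_fs",
                     "U_fx_fp", "S_pp_fp", "S_fp_fa", "S_fa_fs"):
            assert getattr(state, name) == pytest.approx(0.0, abs=1e-12)

    def test_solution_satisfies_conservation(self, params, random_boundary):
        for _ in range(50):
            bc, geom = random_boundary()
            state = ff.solve_control(bc, params, geom)
            res = ff.conservation_residuals(state, bc, params, geom)
            assert abs(res[0]) < 1e-9 * max(1.0, bc.T_fa)
            assert abs(res[1]) < 1e-9 * max(1.0, bc.T_fa)
            assert abs(res[2]) < 1e-12
            assert abs(res[3]) < 1e-12

    def test_matrix_matches_finite_differences(self, params, random_boundary):
        """Columns of the assembled matrix equal the derivatives of the
        conservation laws written with the elementary flow laws."""
        bc, geom = random_boundary()
        A, b = ff.assemble_control_system(bc, params, geom)
        x0 = np.array([-0.4, -0.8, 3e-4, 1e-4])
        h = 1e-7
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            fd = (_independent_conservation_residuals(x0 + e, bc, params, geom)
                  - _independent_conservation_residuals(x0 - e, bc, params, geom)
                  ) / (2 * h)
            np.testing.assert_allclose(A[:, j], fd, rtol=1e-5, atol=1e-8)
        # and the RHS: residual at x is A·x − b
        res = _independent_conservation_residuals(x0, bc, params, geom)
        np.testing.assert_allclose(A @ x0 - b, res, rtol=1e-9, atol=1e-12)

    def test_matches_closed_form(self, params, random_boundary):
        for _ in range(20):
            bc, geom = random_boundary()
            state = ff.solve_control(bc, params, geom)
            cf = ff.solve_control_closed_form(bc, params, geom)
            for name, value in cf.items():
                assert getattr(state, name) == pytest.approx(
                    value, rel=1e-10, abs=1e-14)

    def test_lateral_transfer_identity(self, params, random_boundary):
        """U_fx_fp defined from the xylem side equals the phloem-side
        balance U_fp_fa − U_pp_fp."""
        bc, geom = random_boundary()
        s = ff.solve_control(bc, params, geom)
        assert s.U_fx_fp == pytest.approx(s.U_fp_fa - s.U_pp_fp, abs=1e-10)

    def test_monotone_in_pedicel_potential(self, params):
        geom = ff.geometry_from_weight(57.0)
        flows = []
        for psi in np.linspace(-1.3, -0.5, 9):
            bc = ff.BoundaryConditions(psi_w_pp=psi, C_pp=2.3e-4, T_fa=0.1,
                                       psi_w_fs=-1.3)
            flows.append(ff.solve_control(bc, params, geom).U_px_fx)
        assert np.all(np.diff(flows) > 0)

    def test_nonphysical_solution_warns_not_clips(self, params):
        geom = ff.geometry_from_weight(57.0)
        bc = ff.BoundaryConditions(psi_w_pp=-3.0, C_pp=1e-5, T_fa=0.0,
                                   psi_w_fs=-0.2)
        with pytest.warns(ff.NonPhysicalSolutionWarning):
            state = ff.solve_control(bc, params, geom)
        assert state.C_fp < 0          # reported, not clipped
        assert state.nonphysical


class TestGirdledSolver:
    def test_quiescent(self, params):
        geom = ff.geometry_from_weight(57.0)
        bc = ff.BoundaryConditions(psi_w_pp=-0.6, C_pp=0.0, T_fa=0.0,
                                   psi_w_fs=-0.6)
        state = ff.solve_girdled(bc, params, geom)
        assert state.U_px_fx == pytest.approx(0.0, abs=1e-12)
        assert state.U_fa_fs == pytest.approx(0.0, abs=1e-12)

    def test_phloem_and_sugar_flows_exactly_zero(self, params, random_boundary):
        for _ in range(10):
            bc, geom = random_boundary()
            s = ff.solve_girdled(bc, params, geom)
            # bitwise zero, not approximately zero
            assert s.U_pp_fp == 0.0 and s.U_fp_fa == 0.0
            assert s.S_pp_fp == 0.0 and s.S_fp_fa == 0.0 and s.S_fa_fs == 0.0
            assert s.C_fp == 0.0 and s.C_fa == 0.0

    def test_water_balance_by_construction(self, params, random_boundary):
        bc, geom = random_boundary()
        s = ff.solve_girdled(bc, params, geom)
        assert s.U_px_fx - bc.T_fa == pytest.approx(s.U_fa_fs, abs=1e-12)
        assert s.U_px_fx == pytest.approx(s.U_fx_fa, abs=1e-12)

    def test_limit_of_control_solver(self, params, random_boundary):
        """The girdled system is the K_pp_fp, k_fp_fa, v_fp_fa → 0 limit of
        the full solver."""
        limit = dataclasses.replace(params, K_pp_fp=1e-12, k_fp_fa=1e-12,
                                    v_fp_fa=1e-12)
        for _ in range(10):
            bc, geom = random_boundary()
            g = ff.solve_girdled(bc, params, geom)
            with np.errstate(all="ignore"):
                c = ff.solve_control(bc, limit, geom)
            for name in ("psi_p_fa", "U_px_fx", "U_fx_fa", "U_fa_fs"):
                assert getattr(g, name) == pytest.approx(
                    getattr(c, name), abs=1e-8)


class TestValidation:
    def test_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            dataclasses.replace(ff.reference_parameters(), K_px_fx=-1.0)

    def test_psi_fs_must_be_negative(self):
        with pytest.raises(ValueError):
            ff.reference_parameters().with_psi_fs({"C5_95": 0.1})

    def test_boundary_conditions_validate(self):
        with pytest.raises(ValueError):
            ff.BoundaryConditions(psi_w_pp=-0.5, C_pp=-1e-5, T_fa=0.0,
                                  psi_w_fs=-1.0)
        with pytest.raises(ValueError):
            ff.BoundaryConditions(psi_w_pp=-0.5, C_pp=0.0, T_fa=-0.1,
                                  psi_w_fs=-1.0)

    def test_pedicel_pressures(self):
        bc = ff.BoundaryConditions(psi_w_pp=-0.5, C_pp=2.337e-4, T_fa=0.0,
                                   psi_w_fs=-1.0)
        assert bc.psi_p_px == -0.5
        assert bc.psi_p_pp == pytest.approx(-0.5 + R_GAS * 293.15 * 2.337e-4)

    def test_constants_ordering(self):
        with pytest.raises(ValueError):
            ff.PhysicalConstants(M_S=M_HEXOSE, M_H=M_SUCROSE)
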