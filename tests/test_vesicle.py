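"""Vesicle glutamate-loading model: construction identities, flux contracts,
solver behavior and the ischemia scenario ordering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synglu import vesicle as V
from synglu.constants import FARADAY, N_A


GEOM = V.VesicleGeometry()
PARAMS = V.VesicleParams()
INIT = V.LuminalInitialConditions()
CYT = V.CytosolConditions()


class TestGeometry:
    def test_derived_fields(self):
        # V = 4/3 pi r^3, S = 4 pi r^2, C = c0 S for the 20 nm default
        assert GEOM.volume_L == pytest.approx(3.3510e-20, rel=1e-4)
        assert GEOM.surface_area_cm2 == pytest.approx(5.0265e-11, rel=1e-4)
        assert GEOM.capacitance_F == pytest.approx(5.0265e-17, rel=1e-4)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            V.VesicleGeometry(radius_nm=-1.0)


class TestMoleculeConversion:
    def test_zero_and_round_trip(self):
        assert V.molecules_from_concentration(0.0, GEOM) == 0.0
        c = 173.4357
        n = V.molecules_from_concentration(c, GEOM)
        assert V.concentration_from_molecules(n, GEOM) == c  # exact round trip

    def test_3500_molecules_is_about_173_mM(self):
        # 3500 / (N_A * 3.351e-20 L)
        assert V.concentration_from_molecules(3500.0, GEOM) == pytest.approx(173.44, rel=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            V.molecules_from_concentration(-1.0, GEOM)


class TestSurfaceCorrection:
    def test_zero_potential_identity(self):
        assert V.surface_corrected_concentration(7.7, +1, 0.0, 307.0) == 7.7

    def test_cation_at_outer_leaflet(self):
        # z=+1, psi=-50 mV, T=307 K: exp(50 F / (R T)) ~ 6.62
        f = V.surface_corrected_concentration(1.0, +1, -50.0, 307.0)
        assert f == pytest.approx(6.6193, rel=1e-4)

    @settings(derandomize=True, max_examples=25)
    @given(
        psi=st.floats(-80, 80),
        c=st.floats(1e-3, 200.0),
        temp=st.floats(280.0, 320.0),
    )
    def test_anion_factor_is_reciprocal_of_cation(self, psi, c, temp):
        up = V.surface_corrected_concentration(c, +1, psi, temp)
        dn = V.surface_corrected_concentration(c, -1, psi, temp)
        assert up * dn == pytest.approx(c * c, rel=1e-12)


class TestChargeBalance:
    def test_equal_leaflet_potentials_give_plain_ionic_sum(self):
        p = V.VesicleParams(psi_in_mV=-20.0, psi_out_mV=-20.0)
        b = V.impermeant_charge(INIT, GEOM, p)
        ionic = (
            V.h_conc_mM(INIT.pH_L0)
            + INIT.c_k_L0_mM
            + INIT.c_na_L0_mM
            - INIT.c_cl_L0_mM
            - INIT.c_glut_L0_mM
        )
        assert b == pytest.approx(ionic, abs=1e-12)

    def test_surface_term_magnitude(self):
        # (C/(F V)) * 50 mV ~ 0.777 mM for the 20 nm vesicle
        b_flat = V.impermeant_charge(INIT, GEOM, V.VesicleParams(psi_out_mV=0.0))
        b = V.impermeant_charge(INIT, GEOM, PARAMS)
        assert b_flat - b == pytest.approx(0.7773, rel=1e-3)

    def test_initial_membrane_potential_is_psi_in_minus_psi_out(self):
        # construction identity of the impermeant-charge definition
        b = V.impermeant_charge(INIT, GEOM, PARAMS)
        state = V.VesicleState(
            t=0.0,
            pH_L=INIT.pH_L0,
            c_glut_L_mM=INIT.c_glut_L0_mM,
            c_cl_L_mM=INIT.c_cl_L0_mM,
            c_k_L_mM=INIT.c_k_L0_mM,
        )
        dpsi = V.membrane_potential(state, GEOM, PARAMS, b)
        assert dpsi == pytest.approx(PARAMS.psi_in_mV - PARAMS.psi_out_mV, abs=1e-9)

    def test_charge_sum_equal_to_B_gives_zero(self):
        state = V.VesicleState(t=0.0, pH_L=7.0, c_glut_L_mM=10.0, c_cl_L_mM=30.0, c_k_L_mM=5.0)
        b = (
            V.h_conc_mM(7.0) + 5.0 + PARAMS.c_na_L_mM - 30.0 - 10.0
        )
        assert V.membrane_potential(state, GEOM, PARAMS, b) == pytest.approx(0.0, abs=1e-12)

    def test_one_mM_excess_is_about_64_mV(self):
        state = V.VesicleState(t=0.0, pH_L=7.0, c_glut_L_mM=10.0, c_cl_L_mM=30.0, c_k_L_mM=5.0)
        b = V.h_conc_mM(7.0) + 5.0 + PARAMS.c_na_L_mM - 30.0 - 10.0 - 1.0
        expected = FARADAY * GEOM.volume_L * 1e-3 / GEOM.capacitance_F * 1000.0
        assert V.membrane_potential(state, GEOM, PARAMS, b) == pytest.approx(expected)
        assert expected == pytest.approx(64.32, rel=1e-3)


class TestFluxContracts:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            V.FluxModel(k_vglut=-1.0)

    def test_all_rates_zero_freezes_the_state(self):
        fm = V.FluxModel(
            k_vglut=0, k_vglut_cl=0, k_hleak=0, k_vatpase=0, k_kchan=0, k_nhe=0
        )
        res = V.simulate(fluxes=fm, t_end=500.0)
        assert res.steady_state_reached
        np.testing.assert_allclose(res.n_glut, res.n_glut[0], rtol=1e-9)
        np.testing.assert_allclose(res.pH_L, INIT.pH_L0, rtol=1e-9)
        np.testing.assert_allclose(res.c_cl_L_mM, INIT.c_cl_L0_mM, rtol=1e-9)

    def test_each_flux_vanishes_at_its_own_equilibrium(self):
        fm = V.FluxModel()
        # pick an arbitrary luminal state and compute the dpsi for which each
        # passive flux law must be zero from its Nernst/antiport equilibrium
        state = V.VesicleState(t=0.0, pH_L=6.5, c_glut_L_mM=50.0, c_cl_L_mM=20.0, c_k_L_mM=40.0)
        vt = 1000.0 * 8.314462618 * PARAMS.temperature_K / FARADAY

        def fluxes_at(dpsi):
            return fm.fluxes(state, CYT, dpsi, PARAMS)

        cl_c = V.surface_corrected_concentration(CYT.c_cl_c_mM, -1, PARAMS.psi_out_mV, PARAMS.temperature_K)
        dpsi_cl = vt * math.log(state.c_cl_L_mM / cl_c)
        assert fluxes_at(dpsi_cl)["j_vglut_cl"] == pytest.approx(0.0, abs=1e-12)

        k_c = V.surface_corrected_concentration(CYT.c_k_c_mM, +1, PARAMS.psi_out_mV, PARAMS.temperature_K)
        dpsi_k = vt * math.log(k_c / state.c_k_L_mM)
        assert fluxes_at(dpsi_k)["j_kchan"] == pytest.approx(0.0, abs=1e-12)

        h_c = V.surface_corrected_concentration(V.h_conc_mM(CYT.pH_c), +1, PARAMS.psi_out_mV, PARAMS.temperature_K)
        h_l = V.h_conc_mM(state.pH_L)
        dpsi_h = vt * math.log(h_c / h_l)
        assert fluxes_at(dpsi_h)["j_hleak"] == pytest.approx(0.0, abs=1e-12)

        g_c = V.surface_corrected_concentration(CYT.c_glut_c_mM, -1, PARAMS.psi_out_mV, PARAMS.temperature_K)
        # VGLUT equilibrium: [G]_L/[G]_c,m = ([H]_L/[H]_c,m) exp(2 u)
        dpsi_g = 0.5 * vt * math.log(state.c_glut_L_mM / g_c * h_c / h_l)
        assert fluxes_at(dpsi_g)["j_vglut"] == pytest.approx(0.0, abs=1e-10)

    def test_pump_scales_linearly_with_atpase_scale(self):
        fm = V.FluxModel()
        state = V.VesicleState(t=0.0, pH_L=6.5, c_glut_L_mM=50.0, c_cl_L_mM=20.0, c_k_L_mM=40.0)
        j_full = fm.fluxes(state, CYT, 30.0, PARAMS)["j_vatpase"]
        half = V.CytosolConditions(atpase_scale=0.5)
        j_half = fm.fluxes(state, half, 30.0, PARAMS)["j_vatpase"]
        assert j_half == pytest.approx(0.5 * j_full, rel=1e-12)


class TestRhs:
    def test_zero_fluxes_zero_derivatives(self):
        fm = V.FluxModel(k_vglut=0, k_vglut_cl=0, k_hleak=0, k_vatpase=0, k_kchan=0, k_nhe=0)
        b = V.impermeant_charge(INIT, GEOM, PARAMS)
        y = np.array([INIT.c_glut_L0_mM, INIT.pH_L0, INIT.c_cl_L0_mM, INIT.c_k_L0_mM])
        d = V.rhs(0.0, y, GEOM, PARAMS, CYT, fm, b)
        np.testing.assert_array_equal(d, 0.0)

    def test_pure_pump_pH_rate_matches_single_term_arithmetic(self):
        fm = V.FluxModel(k_vglut=0, k_vglut_cl=0, k_hleak=0, k_vatpase=5.0, k_kchan=0, k_nhe=0)
        b = V.impermeant_charge(INIT, GEOM, PARAMS)
        y = np.array([INIT.c_glut_L0_mM, INIT.pH_L0, INIT.c_cl_L0_mM, INIT.c_k_L0_mM])
        d = V.rhs(0.0, y, GEOM, PARAMS, CYT, fm, b)
        state = V.VesicleState(0.0, pH_L=y[1], c_glut_L_mM=y[0], c_cl_L_mM=y[2], c_k_L_mM=y[3])
        dpsi = V.membrane_potential(state, GEOM, PARAMS, b)
        j = fm.fluxes(state, CYT, dpsi, PARAMS)["j_vatpase"]
        expected = -j / (N_A * GEOM.volume_L * 1e-3) / PARAMS.beta_pH_mM
        assert d[1] == pytest.approx(expected, rel=1e-12)
        assert d[0] == 0.0 and d[2] == 0.0

    def test_vglut_sign_convention(self):
        # a positive glutamate flux raises luminal glutamate and exports H+
        fm = V.FluxModel(k_vglut=1.0, k_vglut_cl=0, k_hleak=0, k_vatpase=0, k_kchan=0, k_nhe=0)
        b = V.impermeant_charge(INIT, GEOM, PARAMS)
        y = np.array([INIT.c_glut_L0_mM, INIT.pH_L0, INIT.c_cl_L0_mM, INIT.c_k_L0_mM])
        d = V.rhs(0.0, y, GEOM, PARAMS, CYT, fm, b)
        assert d[0] > 0  # glutamate accumulates
        assert d[1] > 0  # lumen alkalinizes (protons leave)


class TestSimulate:
    def test_monotone_approach_to_plateau(self, control_run):
        n = control_run.n_glut
        # monotone after the brief initial transient, and saturating
        assert np.all(np.diff(n[10:]) > -1e-6)
        assert control_run.steady_state_reached

    def test_control_anchor_near_3500_molecules(self, control_run):
        n_ss = V.steady_state_glutamate(control_run)
        assert 3000.0 <= n_ss <= 4000.0
        assert n_ss == pytest.approx(3500.0, rel=0.01)

    def test_luminal_acidification_below_cytosolic_pH(self, control_run):
        assert control_run.pH_L[-1] < CYT.pH_c

    def test_determinism_bit_identical(self, control_run):
        res2 = V.simulate()
        np.testing.assert_array_equal(control_run.n_glut, res2.n_glut)
        np.testing.assert_array_equal(control_run.dpsi_mV, res2.dpsi_mV)

    def test_tolerance_halving_changes_result_under_0p1pct(self, control_run):
        tight = V.simulate(rtol=5e-9, atol=5e-11)
        a, b = V.steady_state_glutamate(control_run), V.steady_state_glutamate(tight)
        assert abs(a / b - 1.0) < 1e-3

    def test_doubling_horizon_changes_steady_state_under_0p1pct(self, control_run):
        longer = V.simulate(t_end=6000.0)
        a, b = V.steady_state_glutamate(control_run), V.steady_state_glutamate(longer)
        assert abs(a / b - 1.0) < 1e-3

    def test_not_steady_raises(self):
        res = V.simulate(t_end=20.0)
        assert not res.steady_state_reached
        with pytest.raises(V.NotAtSteadyStateError):
            V.steady_state_glutamate(res)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            V.simulate(t_end=-1.0)
        with pytest.raises(ValueError):
            V.simulate(rtol=0.0)

    def test_charge_consistency_along_trajectory(self, control_run):
        # differencing the algebraic membrane potential must match
        # (F V / C) * d(net charge)/dt within discretization error
        r = control_run
        net = (
            np.array([V.h_conc_mM(p) for p in r.pH_L])
            + r.c_k_L_mM
            + PARAMS.c_na_L_mM
            - r.c_cl_L_mM
            - r.n_glut / GEOM.molecules_per_mM
        )
        dpsi_from_charge = GEOM.mv_per_mM * (net - r.B_mM)
        np.testing.assert_allclose(r.dpsi_mV, dpsi_from_charge, rtol=1e-9)

    def test_zero_vglut_leaves_glutamate_at_initial_level(self):
        fm = V.FluxModel(k_vglut=0.0)
        res = V.simulate(fluxes=fm)
        n0 = V.molecules_from_concentration(INIT.c_glut_L0_mM, GEOM)
        assert res.n_glut[-1] == pytest.approx(n0, abs=0.5)
        assert res.n_glut[-1] < 1.0  # essentially empty


@pytest.fixture(scope="module")
def table():
    return V.run_scenarios()


class TestScenarios:
    def test_empty_override_is_exact_control(self, table):
        row = table[table["name"] == "control"].iloc[0]
        assert row["relative_change"] == 0.0

    @pytest.mark.parametrize(
        "name",
        [
            "cytosolic_acidification",
            "raised_cytosolic_na",
            "raised_cytosolic_cl",
            "lowered_cytosolic_k",
            "lowered_initial_luminal_ph",
            "reduced_atpase",
        ],
    )
    def test_ischemia_like_perturbations_lower_loading(self, table, name):
        row = table[table["name"] == name].iloc[0]
        assert not row["flagged"]
        assert row["relative_change"] < 0.0

    def test_alkalinization_raises_loading(self, table):
        row = table[table["name"] == "cytosolic_alkalinization"].iloc[0]
        assert row["relative_change"] > 0.0

    def test_atpase_off_loads_less_than_control(self, table):
        control_n = table[table["name"] == "control"].iloc[0]["steady_state_n_glut"]
        _, n_off = V.find_steady_state(conditions=V.CytosolConditions(atpase_scale=0.0))
        assert n_off < control_n

    def test_unknown_override_scope_rejected(self):
        with pytest.raises(ValueError):
            V.run_scenarios([V.ScenarioSpec("bad", {"nope.x": 1.0})])
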