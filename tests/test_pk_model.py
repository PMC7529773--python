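import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abpk import (
    MichaelisMentenParams,
    TwoCompartmentParams,
    VmaxScale,
    analytic_linear,
    micro_to_macro,
    model_rhs,
    simulate,
    terminal_half_life_h,
)
from abpk.nca import auc_0_t


class TestMicroToMacro:
    def test_reference_disposition_rates(self, linear_params):
        mac = micro_to_macro(linear_params)
        assert mac.alpha == pytest.approx(40.54, rel=1e-3)
        assert mac.beta == pytest.approx(1.538, rel=1e-3)

    def test_decoupled_limit(self):
        # with no central-to-peripheral transfer the rates approach k10, k21
        p = TwoCompartmentParams(k10=2.0, k12=1e-9, k21=5.0, V1=20.0)
        mac = micro_to_macro(p)
        assert mac.alpha == pytest.approx(5.0, rel=1e-6)
        assert mac.beta == pytest.approx(2.0, rel=1e-6)

    @settings(max_examples=100, derandomize=True)
    @given(
        k10=st.floats(0.01, 50), k12=st.floats(0.01, 50),
        k21=st.floats(0.01, 50), v1=st.floats(1, 500),
    )
    def test_sum_and_product_identities(self, k10, k12, k21, v1):
        p = TwoCompartmentParams(k10, k12, k21, v1)
        mac = micro_to_macro(p)
        assert mac.alpha + mac.beta == pytest.approx(k10 + k12 + k21, rel=1e-10)
        assert mac.alpha * mac.beta == pytest.approx(k10 * k21, rel=1e-10)
        assert mac.alpha >= mac.beta > 0

    def test_intercepts_sum_to_initial_concentration(self, linear_params):
        mac = micro_to_macro(linear_params, dose_mg_per_kg=100.0)
        assert mac.A_coef + mac.B_coef == pytest.approx(100e3 / 25.7, rel=1e-12)


class TestModelRhs:
    def test_zero_state_is_absorbing(self, linear_params, mm_per_kg):
        assert np.allclose(model_rhs([0.0, 0.0], linear_params, mm_per_kg), 0.0)

    def test_saturation_limit(self, linear_params, mm_per_kg):
        # far above Km the saturable term contributes its maximal velocity
        a1 = linear_params.V1 * mm_per_kg.km_ug_per_mL * 1e6
        with_mm = model_rhs([a1, 0.0], linear_params, mm_per_kg)
        without = model_rhs([a1, 0.0], linear_params, None)
        assert without[0] - with_mm[0] == pytest.approx(mm_per_kg.vmax, rel=1e-5)

    def test_linear_drain_rate(self, linear_params):
        d = model_rhs([1000.0, 0.0], linear_params, None)
        assert d[0] == pytest.approx(-16_730.0, rel=1e-12)  # -(k10+k12)*1000
        assert d[1] == pytest.approx(14_270.0, rel=1e-12)

    def test_negative_state_rejected(self, linear_params):
        with pytest.raises(ValueError):
            model_rhs([-1.0, 0.0], linear_params)

    def test_wrong_scale_tag_rejected(self, linear_params, uptake_vitro):
        with pytest.raises(Exception):
            model_rhs([1.0, 0.0], linear_params, uptake_vitro)


class TestSimulate:
    def test_initial_concentration_is_dose_over_v1(self, linear_params):
        prof = simulate(linear_params, None, 100.0, np.array([0.0]))
        assert prof.concentrations[0] == pytest.approx(100e3 / 25.7, rel=1e-9)

    def test_zero_dose_gives_zero_profile(self, linear_params, schedule):
        prof = simulate(linear_params, None, 0.0, schedule)
        assert np.all(prof.concentrations == 0)

    @pytest.mark.parametrize("dose", [1.0, 10.0, 100.0])
    def test_matches_biexponential_oracle(self, linear_params, dose):
        t = np.linspace(1e-4, 2.0, 200)
        sim = simulate(linear_params, None, dose, t)
        ana = analytic_linear(linear_params, dose, t)
        np.testing.assert_allclose(sim.concentrations, ana.concentrations, rtol=1e-6)

    def test_vmax_zero_equals_linear_model(self, linear_params, schedule):
        mm0 = MichaelisMentenParams(23.6, 0.0, VmaxScale.PER_KG, molar_mass=148_000.0)
        sim = simulate(linear_params, mm0, 10.0, schedule)
        ana = analytic_linear(linear_params, 10.0, schedule)
        np.testing.assert_allclose(sim.concentrations, ana.concentrations, rtol=1e-6)

    def test_mass_conservation_without_elimination(self):
        # k10 ~ 0 and Vmax = 0: total amount must be conserved over 10 days
        p = TwoCompartmentParams(k10=1e-12, k12=14.27, k21=25.35, V1=25.7)
        t = np.linspace(0, 10, 50)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda _t, y: model_rhs(np.maximum(y, 0), p, None),
            (0, 10), [1000.0, 0.0], t_eval=t, rtol=1e-10, atol=1e-12, method="LSODA",
        )
        total = sol.y.sum(axis=0)
        np.testing.assert_allclose(total, 1000.0, rtol=1e-8)

    def test_high_km_limit_is_extra_linear_clearance(self, linear_params, schedule):
        # Km -> inf with Vmax/Km fixed adds CL_t/V1 to k10
        cl_t = 500.0  # mL/day/kg
        km_mass = 1e7
        mm = MichaelisMentenParams(
            km_nM=km_mass / (148_000 * 1e-6), vmax=cl_t * km_mass,
            vmax_scale=VmaxScale.PER_KG, molar_mass=148_000.0,
        )
        sim = simulate(linear_params, mm, 10.0, schedule)
        p_eq = TwoCompartmentParams(
            linear_params.k10 + cl_t / linear_params.V1,
            linear_params.k12, linear_params.k21, linear_params.V1,
        )
        ana = analytic_linear(p_eq, 10.0, schedule)
        np.testing.assert_allclose(sim.concentrations, ana.concentrations, rtol=1e-4)

    def test_exposure_superproportional_with_saturable_elimination(
        self, linear_params, mm_per_kg
    ):
        t = np.linspace(1e-4, 2.0, 400)
        auc = {}
        auc_lin = {}
        for dose in (1.0, 10.0, 100.0):
            auc[dose] = auc_0_t(simulate(linear_params, mm_per_kg, dose, t), "linear")
            auc_lin[dose] = auc_0_t(simulate(linear_params, None, dose, t), "linear")
        # dose-normalized AUC grows with dose when the saturable term is active
        assert auc[1.0] / 1 < auc[10.0] / 10 < auc[100.0] / 100
        # and is dose-proportional without it
        assert auc_lin[10.0] / 10 == pytest.approx(auc_lin[1.0], rel=1e-6)
        assert auc_lin[100.0] / 100 == pytest.approx(auc_lin[1.0], rel=1e-6)


class TestTerminalHalfLife:
    def test_reference_value_is_about_11_hours(self, linear_params):
        assert terminal_half_life_h(linear_params) == pytest.approx(10.8, abs=0.05)

    def test_one_compartment_limit(self):
        # with vanishing exchange the slow root carries no amplitude and the
        # observable decay is the fast root at k10 (t1/2 = 6.76 h for 2.46/day)
        p = TwoCompartmentParams(k10=2.46, k12=1e-9, k21=1e-9, V1=25.7)
        mac = micro_to_macro(p, 1.0)
        assert mac.alpha == pytest.approx(2.46, rel=1e-6)
        assert abs(mac.B_coef) < 1e-6 * mac.A_coef
        assert np.log(2) / mac.alpha * 24 == pytest.approx(6.76, abs=0.01)

    def test_reciprocal_scaling_in_beta(self, linear_params):
        mac = micro_to_macro(linear_params)
        # doubling both alpha and beta (scale all rate constants) halves t1/2
        p2 = TwoCompartmentParams(
            2 * linear_params.k10, 2 * linear_params.k12, 2 * linear_params.k21, linear_params.V1
        )
        assert terminal_half_life_h(p2) == pytest.approx(
            terminal_half_life_h(linear_params) / 2, rel=1e-10
        )
        assert np.log(2) / mac.beta * 24 == terminal_half_life_h(linear_params)
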