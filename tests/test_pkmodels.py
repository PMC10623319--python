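"""Structural/device model behaviour against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adsorbkin.datasets import CircuitConfig, DoseEvent, Drug, Port, Route
from adsorbkin.pkmodels import (
    AdsorptionConstantParams,
    AdsorptionSaturableParams,
    OneCompartmentOralParams,
    TwoCompartmentIVParams,
    constant_device_clearance,
    cumulative_adsorbed,
    outlet_concentration,
    saturable_device_clearance,
    solve_profile,
)
from adsorbkin.analysis import cross_device_clearance

CIRCUIT = CircuitConfig(
    blood_flow=120.0, hematocrit=0.33, session_start=0.0, session_duration=6.0
)


def _dose(amount, time=0.0, route=Route.iv_bolus, drug=Drug.MP):
    return DoseEvent(time=time, amount=amount, route=route, drug=drug)


class TestDeviceClearances:
    @pytest.mark.parametrize(
        "k,expected", [(0.0, 0.0), (1.0, 7.2), (0.5, 3.6)]
    )
    def test_constant_clearance_from_blood_flow(self, k, expected):
        params = AdsorptionConstantParams(k_constant=k)
        assert constant_device_clearance(CIRCUIT, params) == pytest.approx(expected)

    def test_constant_clearance_plasma_basis(self):
        params = AdsorptionConstantParams(k_constant=1.0, flow_basis="plasma")
        assert constant_device_clearance(CIRCUIT, params) == pytest.approx(
            7.2 * 0.67
        )

    def test_saturable_clearance_linear_decrease(self):
        p = AdsorptionSaturableParams(CL_max=2.80, A_max=1.15)
        assert saturable_device_clearance(0.0, p) == pytest.approx(2.80)
        assert saturable_device_clearance(1.15, p) == pytest.approx(0.0)
        assert saturable_device_clearance(0.575, p) == pytest.approx(1.40)

    def test_saturable_rejects_overfull_cartridge(self):
        p = AdsorptionSaturableParams(CL_max=2.80, A_max=1.15)
        with pytest.raises(ValueError, match="A_max"):
            saturable_device_clearance(1.16, p)


class TestOutletConcentration:
    def test_no_extraction_and_complete_extraction(self):
        assert outlet_concentration(0.1, 0.0, 4.824) == pytest.approx(0.1)
        assert outlet_concentration(0.1, 4.824, 4.824) == pytest.approx(0.0)

    def test_half_extraction(self):
        assert outlet_concentration(0.100, 2.412, 4.824) == pytest.approx(0.050)

    def test_clearance_above_flow_rejected(self):
        with pytest.raises(ValueError, match="extraction ratio"):
            outlet_concentration(0.1, 5.0, 4.824)

    @given(
        ci=st.floats(1e-6, 10.0),
        ratio=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_outlet_and_cross_device_clearance_are_inverses(self, ci, ratio):
        """Writing an outlet sample from a device CL then re-deriving the
        CL from the pair must be the identity (unit-converted)."""
        fl_ml_min = 120.0 * (1 - 0.33)
        device_cl_ml_min = ratio * fl_ml_min
        co = outlet_concentration(ci, device_cl_ml_min, fl_ml_min)
        back = cross_device_clearance(ci, co, 120.0, 0.33)
        assert back == pytest.approx(device_cl_ml_min, rel=1e-9, abs=1e-12)


class TestSolveProfile:
    def test_iv_bolus_matches_closed_form(self):
        """One-compartment IV bolus: C(t) = (D/V)·exp(−CL/V·t)."""
        params = OneCompartmentOralParams(CL_F=25.0, V_F=35.0)
        times = np.linspace(0.0, 12.0, 40)
        prof = solve_profile(params, None, [_dose(1500.0)], CIRCUIT, times)
        expected = 1500.0 / 35.0 * np.exp(-25.0 / 35.0 * times)
        np.testing.assert_allclose(prof.conc_systemic, expected, rtol=1e-6)

    def test_oral_absorption_with_lag_matches_closed_form(self):
        """First-order absorption with lag: zero before ALAG, Bateman after."""
        p = OneCompartmentOralParams(CL_F=115.0, V_F=2500.0, KA=0.5, ALAG=15.3)
        dose = DoseEvent(time=0.0, amount=10.0, route=Route.oral, drug=Drug.TAC)
        times = np.linspace(0.0, 40.0, 81)
        prof = solve_profile(p, None, [dose], CIRCUIT, times)
        pre = times < 15.3
        assert np.all(prof.conc_systemic[pre] == 0.0)
        ke = p.ke
        dt = times[~pre] - 15.3
        bateman = (
            10.0 * p.KA / (p.V_F * (p.KA - ke)) * (np.exp(-ke * dt) - np.exp(-p.KA * dt))
        )
        np.testing.assert_allclose(prof.conc_systemic[~pre], bateman, rtol=1e-6)

    def test_clamped_concentration_saturation_closed_form(self):
        """With central concentration held ~constant the saturable load obeys
        A(t) = A_max·(1 − exp(−CL_max·C·t/A_max))."""
        C = 0.1  # mg/L
        V = 1e9  # enormous volume pins the concentration
        params = OneCompartmentOralParams(CL_F=1e-9, V_F=V)
        ads = AdsorptionSaturableParams(CL_max=2.80, A_max=1.15)
        times = np.linspace(0.0, 6.0, 25)
        prof = solve_profile(params, ads, [_dose(C * V)], CIRCUIT, times)
        expected = 1.15 * (1.0 - np.exp(-2.80 * C * times / 1.15))
        np.testing.assert_allclose(prof.A_adsorbed, expected, rtol=1e-6, atol=1e-12)

    @pytest.mark.parametrize(
        "structural,adsorption,doses",
        [
            (
                OneCompartmentOralParams(CL_F=500.0, V_F=12000.0, KA=0.5),
                AdsorptionSaturableParams(CL_max=2.80, A_max=1.15),
                [
                    DoseEvent(time=t, amount=600.0, route=Route.oral, drug=Drug.CYA)
                    for t in (0.0, 12.0)
                ],
            ),
            (
                TwoCompartmentIVParams(CL=25.0, V1=35.0, V2=40.0, Q=30.0),
                AdsorptionSaturableParams(CL_max=8.21, A_max=53.4),
                [_dose(1500.0)],
            ),
            (
                OneCompartmentOralParams(CL_F=115.0, V_F=2500.0, KA=0.5, ALAG=2.0),
                AdsorptionConstantParams(k_constant=0.3),
                [
                    DoseEvent(time=0.0, amount=10.0, route=Route.oral, drug=Drug.TAC)
                ],
            ),
        ],
        ids=["oral-saturable", "iv2-saturable", "oral-lag-constant"],
    )
    def test_mass_balance_and_monotone_load(self, structural, adsorption, doses):
        circuit = CircuitConfig(session_start=1.0, session_duration=6.0)
        times = np.linspace(0.0, 14.0, 120)
        prof = solve_profile(structural, adsorption, doses, circuit, times)
        assert np.all(prof.mass_balance_error() < 1e-6)
        loads = prof.A_adsorbed
        assert np.all(np.diff(loads) >= -1e-12)
        if isinstance(adsorption, AdsorptionSaturableParams):
            assert np.all(loads <= adsorption.A_max * (1 + 1e-9))

    def test_superposition_for_linear_model(self):
        """Two doses equal the sum of shifted single-dose profiles when the
        device sub-model is linear (constant extraction)."""
        p = OneCompartmentOralParams(CL_F=50.0, V_F=1200.0, KA=0.5)
        ads = AdsorptionConstantParams(k_constant=0.2)
        circuit = CircuitConfig(session_start=0.0, session_duration=24.0)
        times = np.linspace(0.0, 24.0, 49)
        d1 = DoseEvent(time=0.0, amount=3.0, route=Route.oral, drug=Drug.EVER)
        d2 = DoseEvent(time=12.0, amount=3.0, route=Route.oral, drug=Drug.EVER)
        both = solve_profile(p, ads, [d1, d2], circuit, times)
        single1 = solve_profile(p, ads, [d1], circuit, times)
        single2 = solve_profile(p, ads, [d2], circuit, times)
        np.testing.assert_allclose(
            both.conc_systemic,
            single1.conc_systemic + single2.conc_systemic,
            rtol=1e-6,
            atol=1e-15,
        )

    def test_device_only_active_during_session(self):
        p = OneCompartmentOralParams(CL_F=500.0, V_F=12000.0, KA=0.5)
        ads = AdsorptionSaturableParams(CL_max=2.80, A_max=1.15)
        circuit = CircuitConfig(session_start=2.0, session_duration=6.0)
        times = np.linspace(0.0, 12.0, 121)
        doses = [DoseEvent(time=0.0, amount=600.0, route=Route.oral, drug=Drug.CYA)]
        prof = solve_profile(p, ads, doses, circuit, times)
        before = times <= 2.0
        after = times >= 8.0
        assert np.all(prof.A_adsorbed[before] == 0.0)
        assert np.allclose(
            prof.A_adsorbed[after], prof.A_adsorbed[after][0], rtol=1e-12
        )
        outside = np.isnan(prof.conc_outlet)
        assert np.all(outside == ((times < 2.0) | (times > 8.0)))

    def test_control_circuit_outlet_equals_inlet(self):
        p = OneCompartmentOralParams(CL_F=500.0, V_F=12000.0, KA=0.5)
        circuit = CircuitConfig(device_present=False)
        doses = [DoseEvent(time=0.0, amount=600.0, route=Route.oral, drug=Drug.CYA)]
        times = np.linspace(0.0, 6.0, 13)
        prof = solve_profile(
            p, AdsorptionSaturableParams(CL_max=2.8, A_max=1.15), doses, circuit, times
        )
        assert np.all(prof.A_adsorbed == 0.0)
        np.testing.assert_allclose(prof.conc_outlet, prof.conc_inlet)


class TestCumulativeAdsorbed:
    def test_no_device_run_is_zero(self):
        p = OneCompartmentOralParams(CL_F=50.0, V_F=1200.0, KA=0.5)
        circuit = CircuitConfig(device_present=False)
        prof = solve_profile(
            p,
            None,
            [DoseEvent(time=0.0, amount=3.0, route=Route.oral, drug=Drug.EVER)],
            circuit,
            np.linspace(0, 6, 7),
        )
        assert cumulative_adsorbed(prof) == 0.0

    def test_saturable_run_approaches_capacity(self):
        C, V = 0.5, 1e9
        params = OneCompartmentOralParams(CL_F=1e-9, V_F=V)
        ads = AdsorptionSaturableParams(CL_max=2.80, A_max=1.15)
        circuit = CircuitConfig(session_start=0.0, session_duration=48.0)
        times = np.linspace(0.0, 48.0, 49)
        prof = solve_profile(params, ads, [_dose(C * V)], circuit, times)
        total = cumulative_adsorbed(prof)
        horizon = 1.15 * (1 - np.exp(-2.80 * C * 48.0 / 1.15))
        assert 0.999 * horizon < total <= 1.15

    def test_constant_model_clamped_rectangle_integral(self):
        """Constant extraction at pinned concentration: load = k·flow·C·T."""
        C, V = 0.1, 1e9
        params = OneCompartmentOralParams(CL_F=1e-9, V_F=V)
        ads = AdsorptionConstantParams(k_constant=0.25)
        circuit = CircuitConfig(session_start=0.0, session_duration=6.0)
        prof = solve_profile(
            params, ads, [_dose(C * V)], circuit, np.linspace(0, 6, 13)
        )
        expected = 0.25 * 7.2 * C * 6.0
        assert cumulative_adsorbed(prof) == pytest.approx(expected, rel=1e-6)
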