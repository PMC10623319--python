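"""Estimation engine: Laplace accuracy, self-consistency, two-stage
contracts, model comparison and summary statistics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, optimize

from adsorbkin.datasets import Port, builtin_design
from adsorbkin.estimate import (
    FitResult,
    build_engine,
    compare_models,
    eta_shrinkage,
    fit,
    marginal_ofv,
    two_stage_fit,
    wald_ci,
)
from adsorbkin.simulate import (
    RandomEffectsSpec,
    default_population,
    simulate_study,
)
from conftest import rich_design


class TestWaldCI:
    def test_zero_se_degenerate(self):
        assert wald_ci(1.0, 0.0) == (1.0, 1.0)

    def test_hand_computed_interval(self):
        low, high = wald_ci(0.040, 0.0064)
        assert low == pytest.approx(0.0275, abs=5e-4)
        assert high == pytest.approx(0.0525, abs=5e-4)

    def test_other_levels_use_normal_quantile(self):
        low, high = wald_ci(0.0, 1.0, level=0.90)
        assert high == pytest.approx(1.6449, abs=1e-3)
        assert low == -high


class TestEtaShrinkage:
    def test_all_zero_etas_is_total_shrinkage(self):
        assert eta_shrinkage([0.0, 0.0, 0.0], 0.3) == pytest.approx(100.0)

    def test_full_spread_is_zero_shrinkage(self):
        w = 0.3
        etas = [-w / math.sqrt(2), w / math.sqrt(2)]  # sample SD exactly w
        assert eta_shrinkage(etas, w) == pytest.approx(0.0, abs=1e-9)

    def test_partial_shrinkage_hand_value(self):
        w = 0.3
        a = 0.84 * w / math.sqrt(2)
        assert eta_shrinkage([-a, a], w) == pytest.approx(16.0)

    def test_zero_omega_not_applicable(self):
        assert math.isnan(eta_shrinkage([0.1, -0.1], 0.0))


class TestFitPreconditions:
    def test_single_subject_rejected(self, cya_population):
        des = replace(builtin_design("G2_CYA"), n_intervention=1, n_control=0)
        ds = simulate_study(des, cya_population, seed=1)
        with pytest.raises(ValueError, match="2 subjects"):
            fit(ds, cya_population)


def _noise_free_setup():
    """Zero-IIV, zero-residual CYA study and an additive-error fitting spec
    (fixed sigma), whose OFV optimum is exactly the generating truth."""
    pop = default_population("CYA")
    gen = replace(
        pop,
        random_effects=RandomEffectsSpec(
            omega={}, sigma_prop_pre=0.0, sigma_prop_post=0.0
        ),
    )
    des = rich_design(n_intervention=3, n_control=2, step=0.5)
    ds = simulate_study(des, gen, seed=21, noise=False)
    fit_spec = replace(
        gen,
        random_effects=RandomEffectsSpec(
            omega={}, sigma_prop_pre=0.0, sigma_prop_post=0.0, sigma_add=0.1
        ),
        estimated_flags={"sigma_add": False},
    )
    return ds, fit_spec, pop.structural


class TestSelfConsistency:
    def test_truth_is_stationary_and_recovered(self):
        """On noise-free data with a fixed additive error model, the OFV
        gradient vanishes at the generating parameters and the optimizer
        stays there."""
        ds, fit_spec, truth = _noise_free_setup()
        engine, values = build_engine(ds, fit_spec)

        def f(x):
            v = dict(values)
            v["CL_F"], v["V_F"] = math.exp(x[0]), math.exp(x[1])
            return engine.ofv(v)

        x0 = np.log([truth.CL_F, truth.V_F])
        g = optimize.approx_fprime(x0, f, 1e-7)
        assert np.linalg.norm(g) < 1e-4

        res = fit(ds, fit_spec, initial_values={"CL_F": truth.CL_F, "V_F": truth.V_F})
        assert res.estimates["CL_F"] == pytest.approx(truth.CL_F, rel=1e-6)
        assert res.estimates["V_F"] == pytest.approx(truth.V_F, rel=1e-6)

    def test_five_percent_perturbations_raise_ofv(self):
        ds, fit_spec, truth = _noise_free_setup()
        base = marginal_ofv(ds, fit_spec)
        for name, val in (("CL_F", truth.CL_F), ("V_F", truth.V_F)):
            for fac in (0.95, 1.05):
                perturbed = marginal_ofv(ds, fit_spec, {name: val * fac})
                assert perturbed > base


class TestLaplaceAgainstQuadrature:
    def test_ofv_matches_adaptive_quadrature_on_toy_dataset(self):
        """The per-subject Laplace OFV agrees with exact 1-D quadrature of
        the marginal likelihood within 0.1 units on a 3-subject study."""
        pop = default_population("CYA")
        des = replace(builtin_design("G2_CYA"), n_intervention=3, n_control=0)
        ds = simulate_study(des, pop, seed=17)
        engine, values = build_engine(ds, pop, h_max=0.02)
        laplace = engine.ofv(values)

        exact = 0.0
        for batch in engine.batches:
            for i in range(batch.n):
                def h2_i(eta):
                    e = np.zeros((batch.n, 1))
                    e[i, 0] = eta
                    return float(engine._h2(batch, values, e)[i])

                mode = optimize.minimize_scalar(
                    h2_i, bounds=(-3.0, 3.0), method="bounded",
                    options={"xatol": 1e-10},
                ).x
                h_min = h2_i(mode)
                val, _err = integrate.quad(
                    lambda e: math.exp(-(h2_i(e) - h_min) / 2.0),
                    mode - 6.0, mode + 6.0, limit=200,
                )
                exact += h_min - 2.0 * math.log(val) + math.log(2 * math.pi)
        assert laplace == pytest.approx(exact, abs=0.1)


class TestTwoStage:
    def test_stage2_leaves_stage1_parameters_untouched(self, rich_cya_two_stage):
        s1, s2 = rich_cya_two_stage
        for name in ("V_F", "KA", "ALAG", "omega_CL_F", "sigma_prop_pre"):
            assert s2.estimates[name] == s1.estimates[name]  # bit-for-bit
        assert "V_F" not in s2.estimated_names

    def test_stage2_recovers_adsorption_truth(self, rich_cya_two_stage):
        _s1, s2 = rich_cya_two_stage
        assert 2.80 / 1.5 < s2.estimates["CL_max"] < 2.80 * 1.5
        assert 1.15 / 1.5 < s2.estimates["A_max"] < 1.15 * 1.5

    def test_aic_identity_and_signature(self, rich_cya_two_stage):
        for res in rich_cya_two_stage:
            assert res.aic == pytest.approx(res.ofv + 2 * res.n_estimated)
            assert res.n_estimated == len(res.estimated_names)

    def test_stage1_shrinkage_low_with_rich_sampling(self, rich_cya_two_stage):
        s1, _s2 = rich_cya_two_stage
        assert abs(s1.shrinkage_percent["CL_F"]) < 16.0


class TestStageOneTacRecovery:
    def test_tac_fixed_effects_recovered_with_two_etas(self):
        """Stage 1 on a TAC-like study (IIV on both CL/F and V/F): the
        fixed effects come back within 15% at n=20 with dense sampling."""
        pop = default_population("TAC")
        des = rich_design("G1_TAC", n_intervention=0, n_control=20, step=0.25)
        ds = simulate_study(des, pop, seed=31)
        spec1 = replace(pop, adsorption=None)
        res = fit(ds, spec1)
        assert res.estimates["CL_F"] == pytest.approx(pop.structural.CL_F, rel=0.15)
        assert res.estimates["V_F"] == pytest.approx(pop.structural.V_F, rel=0.15)


class TestCompareModels:
    def test_identical_fits_prefer_nested(self, rich_cya_two_stage):
        _s1, s2 = rich_cya_two_stage
        wider = replace(s2, n_estimated=s2.n_estimated + 1)
        d = compare_models(s2, wider)
        assert d.delta_ofv == 0.0
        assert d.preferred == "nested"

    def test_boundary_delta_is_not_enough(self, rich_cya_two_stage):
        _s1, s2 = rich_cya_two_stage
        extended = replace(s2, n_estimated=s2.n_estimated + 1, ofv=0.0)
        nested = replace(s2, ofv=3.84)
        d = compare_models(nested, extended)
        assert d.delta_ofv == pytest.approx(3.84)
        assert d.preferred == "nested"  # strict inequality required

    def test_different_datasets_rejected(self, rich_cya_two_stage):
        _s1, s2 = rich_cya_two_stage
        other = replace(s2, data_signature=(1, 2, 3.0), n_estimated=s2.n_estimated + 1)
        with pytest.raises(ValueError, match="different datasets"):
            compare_models(s2, other)

    def test_extension_must_add_parameters(self, rich_cya_two_stage):
        _s1, s2 = rich_cya_two_stage
        with pytest.raises(ValueError, match="more parameter"):
            compare_models(s2, s2)
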