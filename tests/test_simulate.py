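"""Synthetic-study generator: distributions, determinism, design fidelity."""

from dataclasses import replace

import numpy as np
import pytest

from adsorbkin.datasets import Drug, Port, builtin_design
from adsorbkin.pkmodels import (
    AdsorptionSaturableParams,
    solve_profile,
)
from adsorbkin.simulate import (
    RandomEffectsSpec,
    apply_residual_error,
    default_population,
    sample_individual,
    simulate_study,
)


class TestSampleIndividual:
    def test_zero_omega_returns_typicals(self):
        pop = default_population("CYA")
        pop = replace(pop, random_effects=replace(pop.random_effects, omega={"CL_F": 0.0}))
        params, etas = sample_individual(pop, seed=1)
        assert params == pop.structural
        assert etas == {"CL_F": 0.0}

    def test_log_normal_spread_matches_omega(self):
        """Monte-Carlo: sample SD of log(CL_i) within 2% of omega=0.3."""
        pop = default_population("CYA")
        rng = np.random.default_rng(12345)
        draws = np.array(
            [np.log(sample_individual(pop, rng)[0].CL_F) for _ in range(10_000)]
        )
        assert np.std(draws) == pytest.approx(0.3, rel=0.02)
        assert np.mean(draws) == pytest.approx(np.log(500.0), abs=0.01)

    def test_same_seed_is_deterministic(self):
        pop = default_population("TAC")
        a, ea = sample_individual(pop, seed=99)
        b, eb = sample_individual(pop, seed=99)
        assert a == b and ea == eb


class TestResidualError:
    def test_zero_sigma_identity(self):
        spec = RandomEffectsSpec(sigma_prop_pre=0.0, sigma_prop_post=0.0)
        assert apply_residual_error(1.23, Port.inlet, spec, 1) == 1.23

    def test_proportional_cv_recovered(self):
        spec = RandomEffectsSpec(sigma_prop_pre=0.20, sigma_prop_post=0.10)
        rng = np.random.default_rng(7)
        draws = apply_residual_error(np.ones(10_000), Port.inlet, spec, rng)
        assert np.std(draws) == pytest.approx(0.20, rel=0.02)
        draws_post = apply_residual_error(np.ones(10_000), Port.outlet, spec, rng)
        assert np.std(draws_post) == pytest.approx(0.10, rel=0.03)

    def test_additive_only_limit_at_zero_concentration(self):
        spec = RandomEffectsSpec(
            sigma_prop_pre=0.20, sigma_prop_post=0.20, sigma_add=0.5
        )
        rng = np.random.default_rng(11)
        draws = apply_residual_error(np.zeros(20_000), Port.inlet, spec, rng)
        # the additive component drives the draws, but negatives are floored
        # at 0, so the observed SD is that of a rectified normal
        rectified_sd = 0.5 * np.sqrt(0.5 - 1 / (2 * np.pi))
        assert np.std(draws) == pytest.approx(rectified_sd, rel=0.03)
        assert np.all(draws >= 0.0)


class TestSimulateStudy:
    def test_group2_structure(self, small_cya_dataset):
        ds = small_cya_dataset
        assert ds.n_subjects == 8
        assert ds.intervention_ids() == [1, 2, 3, 4, 5]
        obs1 = ds.observations(1)
        times = sorted(set(obs1["TIME"]))
        assert times == pytest.approx(
            [168.0 + m / 60 for m in (0, 30, 90, 250, 330)]
        )
        # paired inlet/outlet rows at every sampled time
        for t in times:
            ports = sorted(obs1[obs1["TIME"] == t]["PORT"])
            assert ports == ["IN", "OUT"]
        # controls: single circuit port, treated as systemic
        obs8 = ds.observations(8)
        assert set(obs8["PORT"]) == {"SYS"}

    def test_fixed_seed_bit_identical(self, cya_population):
        des = builtin_design("G2_CYA")
        a = simulate_study(des, cya_population, seed=5)
        b = simulate_study(des, cya_population, seed=5)
        assert a.records.equals(b.records)

    def test_adding_subjects_preserves_existing_ones(self, cya_population):
        """Per-subject substreams: growing the arm never perturbs earlier
        subjects' records."""
        des = builtin_design("G2_CYA")
        small = simulate_study(replace(des, n_intervention=3), cya_population, seed=5)
        large = simulate_study(replace(des, n_intervention=5), cya_population, seed=5)
        for sid in (1, 2, 3):
            a = small.records[small.records["ID"] == sid].reset_index(drop=True)
            b = large.records[large.records["ID"] == sid].reset_index(drop=True)
            assert a.equals(b)

    def test_zero_noise_zero_iiv_matches_solver_output(self, cya_population):
        pop = replace(
            cya_population,
            random_effects=RandomEffectsSpec(
                omega={}, sigma_prop_pre=0.0, sigma_prop_post=0.0
            ),
        )
        des = replace(builtin_design("G2_CYA"), n_intervention=1, n_control=0)
        ds = simulate_study(des, pop, seed=3, noise=False)
        obs = ds.observations(1)
        times = sorted(set(obs["TIME"]))
        prof = solve_profile(
            pop.structural, pop.adsorption, des.dose_events, des.circuit, times
        )
        for i, t in enumerate(times):
            row_in = obs[(obs["TIME"] == t) & (obs["PORT"] == "IN")]
            row_out = obs[(obs["TIME"] == t) & (obs["PORT"] == "OUT")]
            assert row_in["DV"].iloc[0] == pytest.approx(prof.conc_inlet[i], rel=1e-12)
            assert row_out["DV"].iloc[0] == pytest.approx(prof.conc_outlet[i], rel=1e-12)

    def test_vanishing_device_limit(self, cya_population):
        """As A_max → 0 the cartridge saturates instantly and intervention
        inlet profiles converge to the sham-circuit profiles."""
        base = replace(
            cya_population,
            random_effects=RandomEffectsSpec(
                omega={}, sigma_prop_pre=0.0, sigma_prop_post=0.0
            ),
        )
        des = replace(builtin_design("G2_CYA"), n_intervention=1, n_control=1)
        tiny = replace(base, adsorption=AdsorptionSaturableParams(CL_max=2.8, A_max=1e-9))
        ds = simulate_study(des, tiny, seed=3, noise=False)
        inlet = ds.observations(1)
        inlet = inlet[inlet["PORT"] == "IN"].set_index("TIME")["DV"]
        sham = ds.observations(2).set_index("TIME")["DV"]
        common = inlet.index.intersection(sham.index)
        np.testing.assert_allclose(
            inlet.loc[common].to_numpy(), sham.loc[common].to_numpy(), rtol=1e-6
        )

    def test_drug_mismatch_rejected(self, cya_population):
        with pytest.raises(ValueError, match="design is for"):
            simulate_study(builtin_design("G1_TAC"), cya_population, seed=1)


class TestDefaultPopulations:
    def test_cya_saturable_truths(self):
        pop = default_population(Drug.CYA)
        assert pop.adsorption.CL_max == pytest.approx(2.80)
        assert pop.adsorption.A_max == pytest.approx(1.15)

    def test_tac_lag_truth(self):
        assert default_population("TAC").structural.ALAG == pytest.approx(15.3)

    @pytest.mark.parametrize("drug", ["PRED", "BAS"])
    def test_negligible_clearance_drugs_have_no_adsorption(self, drug):
        assert default_population(drug).adsorption is None

    def test_mp_uses_two_compartment_combined_error(self):
        pop = default_population("MP")
        assert pop.structural_kind == "two_cpt_iv"
        assert pop.random_effects.sigma_add > 0

    def test_tac_steady_state_trough_in_target_band(self):
        """Default disposition puts the typical TAC trough inside the
        6–8 ng/mL protocol band (by construction of the defaults)."""
        pop = default_population("TAC")
        des = builtin_design("G1_TAC")
        prof = solve_profile(
            pop.structural, None, des.dose_events, des.circuit,
            [des.circuit.session_start],
        )
        assert 0.006 <= prof.conc_systemic[0] <= 0.008
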