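"""Network model: parameter construction, regulation algebra, ODE dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmnet import (
    PRESETS,
    DrugPerturbation,
    RegulationEdge,
    build_parameters,
    default_edges,
    regulation_factor,
    simulate,
    simulate_chase,
)
from mmnet.network import hours_to_minutes, minutes_to_hours

LN2 = math.log(2.0)


class TestBuildParameters:
    def test_degradation_rate_derivation(self):
        params = build_parameters("initial_model")
        assert params.gamma_p["MYC"] == pytest.approx(LN2 / 0.5)  # ~1.3863/h
        assert params.gamma_p["IRF4"] == pytest.approx(LN2 / 7.0)

    def test_updated_model_irf4_rate(self):
        params = build_parameters("updated_model")
        assert params.gamma_p["IRF4"] == pytest.approx(0.014440, rel=1e-4)

    @pytest.mark.parametrize("preset,irf4_h,myc_h", [
        ("initial_model", 7.0, 0.5),
        ("updated_model", 48.0, 0.5),
        ("KMS-12-BM", 61.0, 1.0),
        ("NCI-H929", 52.0, 22.0 / 60.0),
        ("SKMM-1", 33.0, 0.5),
    ])
    def test_preset_half_lives(self, preset, irf4_h, myc_h):
        params = build_parameters(preset)
        assert params.protein_half_life["IRF4"] == pytest.approx(irf4_h)
        assert params.protein_half_life["MYC"] == pytest.approx(myc_h)

    def test_synthesis_constants_match_degradation(self):
        params = build_parameters("updated_model")
        assert params.k_m == params.gamma_m
        assert params.k_p == params.gamma_p

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError, match="MYC"):
            build_parameters(protein_half_life={"MYC": 0.0})
        with pytest.raises(ValueError, match="IRF4"):
            build_parameters(mrna_half_life={"IRF4": -1.0})

    def test_unknown_preset_lists_valid_ones(self):
        with pytest.raises(ValueError, match="initial_model"):
            build_parameters("no_such_model")

    def test_minutes_hours_round_trip_lossless(self):
        for minutes in (22.0, 30.0):
            assert abs(hours_to_minutes(minutes_to_hours(minutes)) - minutes) < 1e-12


class TestRegulationFactor:
    def test_unit_regulator_gives_unit_factor(self):
        for edge in default_edges():
            assert regulation_factor(edge, 1.0) == pytest.approx(1.0, abs=1e-15)

    def test_default_activation_hand_values(self):
        edge = RegulationEdge("MYC", "IRF4", "activation")  # K=1, h=1, w=2
        # full-strength Hill: g(x) = 2x/(1+x)
        assert regulation_factor(edge, 2.0) == pytest.approx(4.0 / 3.0)
        assert regulation_factor(edge, 0.0) == 0.0

    def test_default_repression_hand_values(self):
        edge = RegulationEdge("PRDM1", "MYC", "repression")  # g(x) = 2/(1+x)
        assert regulation_factor(edge, 0.0) == pytest.approx(2.0)
        assert regulation_factor(edge, 3.0) == pytest.approx(0.5)

    def test_fold_strength_bounds_enforced(self):
        with pytest.raises(ValueError, match="exceeds"):
            RegulationEdge("MYC", "IRF4", "activation", K=0.5, h=1.0, w=2.0)
        with pytest.raises(ValueError, match=">= 1"):
            RegulationEdge("MYC", "IRF4", "activation", w=0.5)

    def test_negative_regulator_rejected(self):
        with pytest.raises(ValueError):
            regulation_factor(default_edges()[0], -0.1)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(0.0, 50.0), y=st.floats(0.0, 50.0),
           K=st.floats(0.2, 5.0), h=st.floats(0.5, 4.0))
    def test_monotone_in_regulator(self, x, y, K, h):
        lo, hi = sorted((x, y))
        w_act = 1.0 + 0.7 * K**h
        act = RegulationEdge("MYC", "IRF4", "activation", K=K, h=h, w=w_act)
        assert regulation_factor(act, lo) <= regulation_factor(act, hi) + 1e-12
        w_rep = 1.0 + 0.7 * K**-h
        rep = RegulationEdge("PRDM1", "MYC", "repression", K=K, h=h, w=w_rep)
        assert regulation_factor(rep, lo) >= regulation_factor(rep, hi) - 1e-12


class TestSimulate:
    def test_unperturbed_steady_state(self, updated_params, default_grid):
        traj = simulate(updated_params, None, time_grid=default_grid)
        assert np.abs(traj.values - 1.0).max() < 1e-6

    def test_zero_epsilon_matches_unperturbed(self, updated_params, default_grid):
        base = simulate(updated_params, None, time_grid=default_grid)
        zero = simulate(updated_params, DrugPerturbation.myc(0.0), time_grid=default_grid)
        np.testing.assert_allclose(zero.values, base.values, atol=1e-9)

    def test_full_myc_block_matches_closed_form(self):
        # KMS-12-BM has distinct MYC mRNA (0.5 h) and protein (1 h) half-lives
        params = build_parameters("KMS-12-BM")
        grid = np.linspace(0.0, 24.0, 49)
        traj = simulate(params, DrugPerturbation.myc(1.0), time_grid=grid)
        gm, gp = params.gamma_m["MYC"], params.gamma_p["MYC"]
        mrna_exact = np.exp(-gm * grid)
        prot_exact = np.exp(-gp * grid) + gp * (np.exp(-gm * grid) - np.exp(-gp * grid)) / (gp - gm)
        assert np.abs(traj.series("MYC", "mRNA") - mrna_exact).max() <= 1e-6
        assert np.abs(traj.series("MYC", "protein") - prot_exact).max() <= 1e-6

    def test_full_irf4_block_mrna_closed_form(self, updated_params):
        grid = np.linspace(0.0, 24.0, 25)
        traj = simulate(updated_params, DrugPerturbation.irf4(1.0), time_grid=grid)
        gm = updated_params.gamma_m["IRF4"]
        assert np.abs(traj.series("IRF4", "mRNA") - np.exp(-gm * grid)).max() <= 1e-6

    def test_larger_epsilon_gives_smaller_target_mrna(self, updated_params, default_grid):
        prev = None
        for eps in (0.2, 0.5, 0.8, 1.0):
            traj = simulate(updated_params, DrugPerturbation.myc(eps), time_grid=default_grid)
            myc = traj.series("MYC", "mRNA")
            if prev is not None:
                assert np.all(myc <= prev + 1e-9)
            prev = myc

    def test_longer_irf4_half_life_never_lowers_irf4_protein(self, default_grid):
        pert = DrugPerturbation.myc(0.8)
        short = simulate(build_parameters("initial_model"), pert, time_grid=default_grid)
        long = simulate(build_parameters("updated_model"), pert, time_grid=default_grid)
        assert np.all(long.series("IRF4", "protein")
                      >= short.series("IRF4", "protein") - 1e-9)

    def test_values_finite_and_nonnegative(self, updated_params, default_grid):
        traj = simulate(updated_params, DrugPerturbation.both(1.0), time_grid=default_grid)
        assert np.all(np.isfinite(traj.values))
        assert np.all(traj.values >= 0)

    def test_onset_delays_drug_effect(self, updated_params):
        grid = np.linspace(0.0, 48.0, 97)
        traj = simulate(updated_params, DrugPerturbation(("MYC",), 0.8, onset_h=24.0),
                        time_grid=grid)
        before = traj.values[grid <= 24.0]
        assert np.abs(before - 1.0).max() < 1e-6
        assert traj.series("MYC", "mRNA")[-1] < 0.5

    def test_invalid_grids_rejected(self, updated_params):
        with pytest.raises(ValueError, match="start at 0"):
            simulate(updated_params, time_grid=np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="increasing"):
            simulate(updated_params, time_grid=np.array([0.0, 2.0, 1.0]))

    def test_no_extrapolation_outside_span(self, updated_params):
        traj = simulate(updated_params, t_max=24.0)
        with pytest.raises(ValueError, match="outside"):
            traj.at(30.0)


class TestSimulateChase:
    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_protein_decay_is_exact_exponential(self, preset):
        params = build_parameters(preset)
        grid = np.linspace(0.0, 72.0, 37)
        traj = simulate_chase(params, time_grid=grid)
        for species in ("MYC", "IRF4", "PRDM1"):
            gp = params.gamma_p[species]
            np.testing.assert_allclose(traj.series(species, "protein"),
                                       np.exp(-gp * grid), atol=1e-12)

    def test_protein_halves_at_its_half_life(self, updated_params):
        for species in ("MYC", "IRF4", "PRDM1"):
            th = updated_params.protein_half_life[species]
            traj = simulate_chase(updated_params, time_grid=np.array([0.0, th]))
            assert abs(traj.series(species, "protein")[-1] - 0.5) < 1e-9

    def test_updated_model_irf4_at_72h(self, updated_params):
        traj = simulate_chase(updated_params, time_grid=np.array([0.0, 72.0]))
        assert traj.series("IRF4", "protein")[-1] == pytest.approx(2 ** (-72 / 48), abs=1e-9)

    def test_mrna_keeps_evolving(self, updated_params, default_grid):
        # regulator proteins decay, so regulated transcription drifts off 1
        traj = simulate_chase(updated_params, time_grid=default_grid)
        assert np.abs(traj.series("IRF4", "mRNA") - 1.0).max() > 0.05
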