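import numpy as np
import pytest

from crossfba import (
    ScreenConfig,
    SimulationConfig,
    call_essential,
    make_environment,
    read_screen_tsv,
    run_screen,
    simulate_community,
    write_screen_tsv,
)


def _records_for(result, reaction_id):
    return {r.condition: r for r in result.records if r.reaction_id == reaction_id}


class TestCallEssential:
    def _traj(self, toy_s, gain_scale, study_sim):
        env = make_environment("competition")
        traj = simulate_community([toy_s], env, study_sim)
        traj.biomass["S"] = traj.biomass["S"].copy()
        traj.biomass["S"][-1] = traj.biomass["S"][0] + gain_scale
        return traj

    def test_threshold_behavior(self, toy_s, study_sim):
        ref = self._traj(toy_s, 1.0, study_sim)
        assert call_essential(self._traj(toy_s, 0.01, study_sim), ref, 0.02, "S")
        assert not call_essential(self._traj(toy_s, 0.5, study_sim), ref, 0.02, "S")

    def test_unperturbed_vs_itself_not_essential(self, toy_s, study_sim):
        ref = self._traj(toy_s, 1.0, study_sim)
        assert not call_essential(ref, ref, 0.02, "S")

    def test_shrinking_reference(self, toy_e, study_sim):
        # the auxotroph alone only decays; a mutant that also decays is
        # called essential, one that somehow gains is not
        env = make_environment("cooperation")
        ref = simulate_community([toy_e], env, study_sim)
        assert ref.biomass_gain("E") < 0
        assert call_essential(ref, ref, 0.02, "E")

    def test_mismatched_horizons_rejected(self, toy_s, study_sim):
        import dataclasses

        short = dataclasses.replace(study_sim, duration=5.0)
        env = make_environment("competition")
        t1 = simulate_community([toy_s], env, study_sim)
        t2 = simulate_community([toy_s], env, short)
        with pytest.raises(ValueError):
            call_essential(t1, t2, 0.02, "S")


class TestScreenStructure:
    def test_cardinality(self, toy_screen):
        result, config, _ = toy_screen
        # 12 focal reactions x 2 pair conditions
        assert len(result.records) == 24
        assert set(result.unperturbed) == {"cooperation", "competition"}
        pairs = {(r.reaction_id, r.condition) for r in result.records}
        assert len(pairs) == 24

    def test_unperturbed_metrics_identity(self, toy_screen):
        """Feeding the unperturbed outcome through the metrics must give
        (ECD, %E, BM) = (0, 1, 1) exactly."""
        from crossfba import ecd, normalized_bm, normalized_percent_e

        result, _, _ = toy_screen
        for condition, (Eu, Su) in result.unperturbed.items():
            assert ecd(Eu, Su, Eu, Su) == 0.0
            assert normalized_percent_e(Eu, Su, Eu, Su) == pytest.approx(1.0)
            assert normalized_bm(Eu, Su, Eu, Su) == pytest.approx(1.0)

    def test_biomass_knockout_essential_everywhere(self, toy_screen):
        result, _, _ = toy_screen
        recs = _records_for(result, "BIOMASS")
        assert recs["cooperation"].essential_monoculture
        assert recs["cooperation"].essential_cooperation
        assert recs["competition"].essential_competition
        # the partner keeps growing on supplemented medium, but in the
        # mutualism it only gets the maintenance trickle of acetate
        s_gain_coop = recs["cooperation"].S_final - 3e-7
        s_gain_comp = recs["competition"].S_final - 3e-7
        assert s_gain_comp > 5 * max(s_gain_coop, 0)

    def test_oxygen_knockout_shifts_composition_to_partner(self, toy_screen):
        result, _, _ = toy_screen
        recs = _records_for(result, "EX_o2")
        for condition in ("cooperation", "competition"):
            assert not recs[condition].essential_monoculture
            assert recs[condition].pctE_norm < 1

    def test_monoculture_and_competition_essentiality_coincide(self, toy_screen):
        """Competition medium equals the monoculture medium, so the two
        essentiality calls must name the same reactions."""
        result, _, _ = toy_screen
        mono = {r.reaction_id for r in result.records if r.essential_monoculture}
        comp = {r.reaction_id for r in result.records if r.essential_competition}
        assert mono == comp

    def test_cooperation_adds_maintenance_essentiality(self, toy_screen):
        result, _, _ = toy_screen
        mono = {r.reaction_id for r in result.records if r.essential_monoculture}
        coop = {r.reaction_id for r in result.records if r.essential_cooperation}
        assert coop >= mono
        assert "MAINT" in coop - mono

    def test_provenance_carries_checksums_and_parameters(self, toy_screen, toy_pair):
        result, _, _ = toy_screen
        assert result.provenance["focal_checksum"] == toy_pair[0].checksum()
        assert result.provenance["partner_checksum"] == toy_pair[1].checksum()
        assert result.provenance["dt_h"] == 0.1
        assert result.provenance["duration_h"] == 10.0


class TestScreenDeterminism:
    def test_permuted_mutant_order_gives_identical_records(self, toy_pair):
        e_model, s_model = toy_pair
        config = ScreenConfig(simulation=SimulationConfig(duration=2.0))
        forward = run_screen(e_model, s_model, config)
        rng = np.random.default_rng(3)
        order = [r.id for r in e_model.reactions]
        rng.shuffle(order)
        shuffled = run_screen(e_model, s_model, config, mutant_order=order)
        assert forward.records == shuffled.records

    def test_bad_mutant_order_rejected(self, toy_pair):
        config = ScreenConfig(simulation=SimulationConfig(duration=1.0))
        with pytest.raises(KeyError):
            run_screen(*toy_pair, config, mutant_order=["BIOMASS"])


class TestScreenConfigValidation:
    def test_thresholds_must_be_fractions(self):
        with pytest.raises(ValueError):
            ScreenConfig(essentiality_threshold=0.0)
        with pytest.raises(ValueError):
            ScreenConfig(substantive_threshold=1.5)

    def test_conditions_checked(self):
        with pytest.raises(ValueError):
            ScreenConfig(conditions=())
        with pytest.raises(ValueError):
            ScreenConfig(conditions=("mutualism",))


class TestTsvRoundTrip:
    def test_screen_tsv_round_trip(self, toy_screen, tmp_path):
        result, _, _ = toy_screen
        path = tmp_path / "screen.tsv"
        write_screen_tsv(result, path)
        back = read_screen_tsv(path)
        assert back.unperturbed.keys() == result.unperturbed.keys()
        for cond in result.unperturbed:
            assert back.unperturbed[cond] == pytest.approx(result.unperturbed[cond])
        assert len(back.records) == len(result.records)
        for a, b in zip(back.records, result.records):
            assert a.reaction_id == b.reaction_id
            assert a.condition == b.condition
            assert a.ECD == pytest.approx(b.ECD, rel=1e-10)
            assert a.essential_cooperation == b.essential_cooperation
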