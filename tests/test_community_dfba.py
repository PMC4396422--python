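import numpy as np
import pytest

from crossfba import (
    Environment,
    SimulationConfig,
    SpeciesState,
    make_environment,
    simulate_community,
    step_community,
    uptake_bound,
)


@pytest.fixture()
def coop_env():
    return make_environment("cooperation")


class TestUptakeBound:
    def test_empty_pool_gives_zero(self, coop_env, study_sim):
        assert uptake_bound(0.0, coop_env, study_sim) == 0.0

    def test_half_saturation_at_km(self, coop_env, study_sim):
        # Km = 10 uM = 0.01 mmol/L; the pool holding that concentration
        pool = 0.01 * coop_env.volume
        assert uptake_bound(pool, coop_env, study_sim) == pytest.approx(5.0)

    def test_unlimited_returns_vmax(self, study_sim):
        env = make_environment("competition")
        assert uptake_bound(0.0, env, study_sim, metabolite_id="ac_e") == 10.0

    def test_monotone_in_pool(self, coop_env, study_sim):
        pools = np.linspace(0, 1e-4, 50)
        bounds = [uptake_bound(p, coop_env, study_sim) for p in pools]
        assert all(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:]))
        assert max(bounds) <= study_sim.vmax


class TestStepCommunity:
    def test_pool_decrement_equals_flux_times_biomass_dt(self, toy_e, coop_env, study_sim):
        states = [SpeciesState(model=toy_e, biomass=3e-7)]
        new_states, new_env, solutions = step_community(states, coop_env, study_sim)
        v = solutions["E"].fluxes["EX_lcts"]
        expected = coop_env.pools["lcts_e"] + v * 3e-7 * study_sim.dt
        assert new_env.pools["lcts_e"] == pytest.approx(expected, rel=1e-12)

    def test_euler_biomass_update(self, toy_pair, study_sim):
        """With saturating uncapped nutrients, one step multiplies biomass by
        (1 + (mu - d) dt) with mu straight from the FBA solve."""
        e_model, s_model = toy_pair
        env = Environment(
            volume=1.25e-7,
            pools={"lcts_e": 0.0, "o2_e": 0.0, "ac_e": 0.0, "met_e": 0.0},
            unlimited={"lcts_e", "o2_e", "ac_e", "met_e"},
        )
        states = [SpeciesState(e_model, 3e-7), SpeciesState(s_model, 3e-7)]
        new_states, _, solutions = step_community(states, env, study_sim)
        for st, new in zip(states, new_states):
            mu = solutions[st.model.species_id].growth_rate
            assert mu > 0
            assert new.biomass == pytest.approx(
                st.biomass * (1 + (mu - study_sim.death_rate) * study_sim.dt), rel=1e-12
            )

    def test_death_only_decay_without_methionine(self, toy_e, coop_env, study_sim):
        states = [SpeciesState(model=toy_e, biomass=3e-7)]
        new_states, _, solutions = step_community(states, coop_env, study_sim)
        assert solutions["E"].growth_rate == 0.0
        assert new_states[0].biomass == pytest.approx(
            3e-7 * (1 - 0.01 * 0.1), rel=1e-12
        )


class TestSimulateCommunity:
    def test_auxotroph_alone_strictly_decays(self, toy_e, coop_env, study_sim):
        traj = simulate_community([toy_e], coop_env, study_sim)
        b = traj.biomass["E"]
        assert np.all(np.diff(b) < 0)
        assert b[-1] < b[0]

    def test_cooperative_pair_grows_with_e_dominant(self, coop_traj):
        for sid in ("E", "S"):
            assert coop_traj.final_biomass(sid) > coop_traj.initial_biomass(sid)
        e_frac = coop_traj.final_biomass("E") / (
            coop_traj.final_biomass("E") + coop_traj.final_biomass("S")
        )
        assert e_frac > 0.5

    def test_unlimited_single_species_matches_closed_form(self, toy_s, study_sim):
        """Geometric-growth limit: constant mu = 1.5, so after n steps
        B = B0 (1 + (mu - d) dt)^n exactly."""
        env = Environment(
            volume=1.25e-7,
            pools={"ac_e": 0.0, "o2_e": 0.0},
            unlimited={"ac_e", "o2_e"},
        )
        traj = simulate_community([toy_s], env, study_sim, initial_biomass=3e-7)
        n = study_sim.n_steps()
        expected = 3e-7 * (1 + (1.5 - 0.01) * 0.1) ** n
        assert traj.final_biomass("S") == pytest.approx(expected, rel=1e-9)
        assert np.allclose(traj.growth_rates["S"], 1.5, atol=1e-9)

    def test_exchange_bookkeeping_exact(self, toy_pair, study_sim):
        """For every finite pool and step, the pool change equals
        sum_species flux * biomass * dt to 1e-12 relative."""
        config = SimulationConfig(tolerance=0.0)
        traj = simulate_community(
            list(toy_pair), make_environment("cooperation"), config
        )
        for k, step_fluxes in enumerate(traj.exchange_fluxes):
            for met, series in traj.pools.items():
                delta = series[k + 1] - series[k]
                expected = 0.0
                for sid in sorted(step_fluxes):
                    model = dict(zip(("E", "S"), toy_pair))[sid]
                    ex = model.exchange_for(met)
                    if ex is not None:
                        expected += (
                            step_fluxes[sid][ex.id]
                            * traj.biomass[sid][k]
                            * config.dt
                        )
                scale = max(abs(series[k]), abs(series[k + 1]), abs(expected), 1e-30)
                assert abs(delta - expected) <= 1e-12 * scale

    def test_non_negativity(self, coop_traj):
        for series in coop_traj.biomass.values():
            assert np.all(series >= 0)
        for series in coop_traj.pools.values():
            assert np.all(series >= 0)

    def test_species_order_invariance(self, toy_pair, study_sim):
        e_model, s_model = toy_pair
        t1 = simulate_community([e_model, s_model], make_environment("cooperation"), study_sim)
        t2 = simulate_community([s_model, e_model], make_environment("cooperation"), study_sim)
        for sid in ("E", "S"):
            assert np.array_equal(t1.biomass[sid], t2.biomass[sid])
        for met in t1.pools:
            assert np.array_equal(t1.pools[met], t2.pools[met])

    def test_limiting_reagent_yield_ceiling(self, toy_pair, toy_params, coop_traj):
        """Total biomass gain is bounded by the ATP obtainable from the
        initial lactose pool, counting the acetate relay to the partner."""
        p = toy_params
        atp_per_lactose = (
            p.atp_per_lactose_aerobic + p.acetate_per_lactose * p.atp_per_acetate
        )
        ceiling = 1.2e-5 * atp_per_lactose / p.atp_per_biomass
        gain = coop_traj.biomass_gain("E") + coop_traj.biomass_gain("S")
        assert 0 < gain < ceiling

    def test_duration_must_divide_by_dt(self, toy_e, study_sim):
        bad = SimulationConfig(dt=0.3, duration=1.0)
        with pytest.raises(ValueError):
            simulate_community([toy_e], make_environment("cooperation"), bad)

    def test_trajectory_frame_and_csv(self, coop_traj, tmp_path):
        df = coop_traj.to_frame()
        assert list(df.columns[:3]) == ["time_h", "species_id", "biomass_g"]
        assert len(df) == 2 * len(coop_traj.times)
        out = tmp_path / "traj.csv"
        coop_traj.write_csv(out, provenance={"note": "test"})
        text = out.read_text()
        assert text.startswith("# note: test\n")
        assert text.count("\n") == 2 + 2 * len(coop_traj.times)

    def test_random_update_order_is_seeded(self, toy_pair, study_sim):
        import dataclasses

        cfg = dataclasses.replace(study_sim, update_order="random", seed=7, duration=2.0)
        t1 = simulate_community(list(toy_pair), make_environment("cooperation"), cfg)
        t2 = simulate_community(list(toy_pair), make_environment("cooperation"), cfg)
        for sid in ("E", "S"):
            assert np.array_equal(t1.biomass[sid], t2.biomass[sid])
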