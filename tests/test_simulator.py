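"""Detailed stochastic evolution simulator: operations and invariants."""
import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from pfevo.environment import Environment
from pfevo.lumped import (MutationSpec, ancestral_half_life, class_fitnesses,
                          simulate_lumped)
from pfevo.simulator import (MUT_ANC, MUT_G, MUT_K, SimConfig, Simulator,
                             SummaryStats, stochastic_step, summarize_ensemble)
from pfevo.switching import SwitchingParams, dominant_growth_rate


def make_sim(**over) -> Simulator:
    return Simulator(config=SimConfig(**over))


class TestDrugUptake:
    def test_zero_external_stays_zero(self, envs):
        sim = make_sim()
        st = sim.new_population()
        sim.update_drug_uptake(st, envs["D0Z0"], 100.0)
        assert st.C_int == 0.0 and st.Z_int == 0.0

    def test_relaxes_to_external_equilibrium(self, envs):
        sim = make_sim()
        st = sim.new_population()
        sim.update_drug_uptake(st, envs["D2Z2"], 1000.0)
        assert st.C_int == pytest.approx(2.0, rel=1e-9)
        assert st.Z_int == pytest.approx(2.0, rel=1e-9)

    def test_two_half_steps_equal_one_full_step(self, envs):
        sim = make_sim()
        a = sim.new_population()
        sim.update_drug_uptake(a, envs["D2Z2"], 3.0)
        b = sim.new_population()
        sim.update_drug_uptake(b, envs["D2Z2"], 1.5)
        sim.update_drug_uptake(b, envs["D2Z2"], 1.5)
        assert a.C_int == pytest.approx(b.C_int, abs=1e-12)
        assert a.Z_int == pytest.approx(b.Z_int, abs=1e-12)

    def test_negative_dt_rejected(self, envs):
        sim = make_sim()
        with pytest.raises(ValueError):
            sim.update_drug_uptake(sim.new_population(), envs["D0Z0"], -1.0)


class TestGrowthStep:
    def test_drug_free_deterministic_growth(self, envs):
        sim = make_sim(dt_h=12.0)
        st = sim.new_population(1e6)
        sim.step_growth(st, envs["D0Z0"], 12.0, np.random.default_rng(0))
        expected = 1e6 * math.exp(sim.params.gamma0 * 12.0)
        assert st.total == pytest.approx(expected, rel=1e-9)

    def test_knockout_cells_never_switch_on(self, envs):
        """K lineages stay Off for the whole run (no induction cost)."""
        sim = make_sim(p_G=0.0, p_T=0.0, duration_days=2.0)
        rng = np.random.default_rng(2)
        st = sim.new_population()
        env = envs["D2Z0"]
        for _ in range(480):
            sim.update_drug_uptake(st, env, 0.1)
            births = sim.step_growth(st, env, 0.1, rng)
            sim.inject_mutations(st, env, births, rng)
            k = st.mut_type == MUT_K
            assert np.all(st.n_H[k] == 0.0)

    def test_deterministic_limit_matches_dominant_eigenvalue(self, envs):
        """All-ODE threshold, no mutation: long-run log-growth equals the
        two-state dominant eigenvalue."""
        sim = make_sim(stochastic_size_threshold=0.0, mu_no_z=0.0,
                       mu_with_z=0.0, deterministic_resuspension=True)
        env = envs["D2Z0"]
        rng = np.random.default_rng(0)
        st = sim.new_population()
        st.C_int, st.Z_int = env.dox, env.zeo   # skip the uptake transient
        # relax onto the dominant eigenvector first
        for _ in range(2000):
            sim.step_growth(st, env, 0.1, rng)
            if st.total > 1e12:
                st.n_L *= 1e-8
                st.n_H *= 1e-8
        n0 = st.total
        for _ in range(100):
            sim.step_growth(st, env, 0.1, rng)
        observed = math.log(st.total / n0) / 10.0
        from pfevo.fitness import cellular_fitness
        g_L = float(cellular_fitness(10.0, env, sim.params))
        g_H = float(cellular_fitness(1000.0, env, sim.params))
        lam = dominant_growth_rate(SwitchingParams(
            g_L=g_L, g_H=g_H, r=sim.switching.r_of_dox(2.0),
            f=sim.switching.f, r_max=None))
        assert observed == pytest.approx(lam, rel=1e-6)


class TestStochasticStep:
    def test_extinction_matches_birth_death_closed_form(self):
        """A single cell under linear birth-death: extinction probability
        by time t is d(e^{(b-d)t}-1)/(b e^{(b-d)t}-d)."""
        b, d, t_end, dt = 0.30, 0.20, 24.0, 0.05
        rng = np.random.default_rng(99)
        n_rep = 4000
        n = np.ones(n_rep, dtype=np.int64)
        zeros = np.zeros(n_rep)
        for _ in range(int(t_end / dt)):
            n, _, _ = stochastic_step(rng, n, np.zeros_like(n),
                                      b, zeros + d, 0.0, 0.0, 0.0, 0.0, dt)
        p_obs = float(np.mean(n == 0))
        g = b - d
        p_true = d * (math.exp(g * t_end) - 1) / (b * math.exp(g * t_end) - d)
        se = math.sqrt(p_true * (1 - p_true) / n_rep)
        assert abs(p_obs - p_true) < 3 * se

    def test_pure_birth_mean_growth(self):
        rng = np.random.default_rng(1)
        n = np.full(2000, 10, dtype=np.int64)
        for _ in range(100):
            n, _, _ = stochastic_step(rng, n, np.zeros_like(n),
                                      0.2, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1)
        expected = 10 * math.exp(0.2 * 10.0)
        se = n.std() / math.sqrt(n.size)
        assert abs(n.mean() - expected) < 3 * se


class TestMutationInjection:
    def test_zero_rate_never_mutates(self, envs):
        sim = make_sim(mu_no_z=0.0, mu_with_z=0.0)
        st = sim.new_population()
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert sim.inject_mutations(st, envs["D2Z0"], (1e5, 1e4), rng) == 0
        assert st.n_alleles == 1

    def test_poisson_mean_matches_rate(self, envs):
        sim = make_sim()
        rng = np.random.default_rng(8)
        births = 5e4
        mu = sim.config.mu_with_z
        counts = []
        for _ in range(3000):
            st = sim.new_population()
            st.Z_int = 2.0
            counts.append(sim.inject_mutations(st, envs["D0Z2"], (births, 0.0),
                                               rng))
        lam = mu * births
        se = math.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_type_fractions_match_multinomial(self, envs):
        sim = make_sim()
        rng = np.random.default_rng(9)
        st = sim.new_population()
        st.Z_int = 2.0
        while st.n_alleles < 10_001:
            sim.inject_mutations(st, envs["D0Z2"], (1e6, 0.0), rng)
        types = st.mut_type[1:10_001]
        n = len(types)
        for code, p in ((1, sim.config.p_K), (2, sim.config.p_T),
                        (3, sim.config.p_G)):
            obs = np.mean(types == code)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * se, code

    def test_effect_size_invariants(self, envs):
        """K cannot switch; T scales switching and On expression by the
        same tweak; G multiplies the kill constant, capped."""
        sim = make_sim()
        rng = np.random.default_rng(10)
        st = sim.new_population()
        st.Z_int = 2.0
        while st.n_alleles < 2001:
            sim.inject_mutations(st, envs["DiZ2"], (1e6, 1e5), rng)
        t = st.mut_type[1:]
        assert np.all(st.r_mult[1:][t == MUT_K] == 0.0)
        tw = st.r_mult[1:][t == 2]
        assert np.all((tw > 0) & (tw < 1))
        assert np.allclose(st.log10_f_on[1:][t == 2], 1.0 + 2.0 * tw)
        gm = st.res_mult[1:][t == MUT_G]
        assert np.all(gm >= 1.0)

    def test_mutants_inherit_parent_state_proportionally(self, envs):
        sim = make_sim(p_G=1.0, p_T=0.0)
        rng = np.random.default_rng(11)
        st = sim.new_population()
        st.Z_int = 2.0
        while st.n_alleles < 4001:
            sim.inject_mutations(st, envs["DiZ2"], (3e5, 7e5), rng)
        on = st.n_H[1:4001].sum() / 4000
        se = math.sqrt(0.7 * 0.3 / 4000)
        assert abs(on - 0.7) < 3 * se


class TestResuspension:
    def test_below_bottleneck_unchanged(self, envs):
        sim = make_sim()
        st = sim.new_population(5e5)
        before = st.total
        sim.resuspend(st, envs["D0Z0"], np.random.default_rng(0))
        assert st.total == before

    def test_exact_bottleneck_after_dilution(self, envs):
        sim = make_sim()
        st = sim.new_population(7.3e6)
        sim.resuspend(st, envs["D0Z0"], np.random.default_rng(0))
        assert st.total == sim.config.bottleneck

    def test_frequency_preserved_in_expectation(self, envs):
        """An allele at 30% keeps its expected frequency through the
        multinomial bottleneck (3 SE over 2000 resuspensions)."""
        sim = make_sim(bottleneck=1e4)
        rng = np.random.default_rng(12)
        freqs = []
        for _ in range(2000):
            st = sim.new_population(7e6)
            st.append(ids=np.array([1]), mut_type=np.array([MUT_G], dtype=np.int8),
                      r_mult=np.array([1.0]), res_u=np.array([0.5]),
                      res_mult=np.array([2.0]), log10_f_on=np.array([3.0]),
                      preexisting=np.array([False]),
                      n_L=np.array([3e6]), n_H=np.array([0.0]))
            sim.resuspend(st, envs["D0Z0"], rng)
            freqs.append(st.frequencies()[1] if st.n_alleles > 1 else 0.0)
        se = np.std(freqs) / math.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.3) < 3 * se


class TestRunReplicate:
    def test_mu_zero_stays_ancestral(self, envs):
        sim = make_sim(mu_no_z=0.0, mu_with_z=0.0, duration_days=3.0)
        traj, stats = sim.run_replicate(envs["D2Z0"], seed=5)
        assert stats.half_life_days == math.inf
        assert stats.n_established == 0
        assert stats.mutant_fraction == 0.0
        assert (traj["mut_type"] == "ancestral").all()
        assert np.allclose(traj["frequency"], 1.0)

    def test_same_seed_is_bit_identical(self, envs):
        sim = make_sim(duration_days=4.0)
        t1, s1 = sim.run_replicate(envs["D0Z2"], seed=77)
        t2, s2 = sim.run_replicate(envs["D0Z2"], seed=77)
        pd.testing.assert_frame_equal(t1, t2)
        assert s1.half_life_days == s2.half_life_days
        assert s1.n_established == s2.n_established
        assert s1.type_fractions == s2.type_fractions
        assert s1.mutant_fraction == s2.mutant_fraction

    def test_frequencies_sum_to_one_daily(self, envs):
        sim = make_sim(duration_days=6.0)
        traj, _ = sim.run_replicate(envs["D0Z2"], seed=3)
        sums = traj.groupby("day")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_trajectory_records_types_and_flags(self, envs):
        sim = make_sim(duration_days=6.0)
        traj, _ = sim.run_replicate(envs["D0Z2"], seed=3)
        assert set(traj.columns) == {"day", "allele_id", "mut_type",
                                     "preexisting", "frequency"}
        assert not traj["preexisting"].any()   # no pre-phase here


class TestPreexistingVariant:
    def test_zero_pre_phase_rate_gives_zero_contribution(self, envs):
        sim = make_sim(mu_no_z=0.0, duration_days=3.0)
        _, stats = sim.run_preexisting_variant(envs["D0Z2"], seed=4)
        assert stats.preexisting_fraction == 0.0

    def test_phase_bookkeeping_separates_origins(self, envs):
        """Mutations from the neutral pre-phase carry the preexisting
        flag; in-run mutations do not (checked via origin times)."""
        sim = make_sim(duration_days=2.0, mu_no_z=10 ** -4.5,
                       mu_with_z=10 ** -4.5)
        traj, stats = sim.run_replicate(envs["D0Z0"], seed=6,
                                        preexisting_hours=24.0)
        day2 = traj[traj["day"] == 2]
        pre = day2[day2["preexisting"]]
        new = day2[(~day2["preexisting"]) & (day2["mut_type"] != "ancestral")]
        assert len(pre) > 0 and len(new) > 0
        assert 0.0 <= stats.preexisting_fraction <= 1.0


class TestEnsemble:
    def test_identical_replicates_have_zero_sem(self):
        s = SummaryStats(half_life_days=4.0, n_established=2,
                         type_fractions={"K": 0.5, "T": 0.0, "G": 0.0},
                         mutant_fraction=0.6)
        ens = summarize_ensemble([s, s, s])
        assert ens.half_life_sem == 0.0 and ens.n_established_sem == 0.0

    def test_two_replicates_mean_and_sem(self):
        mk = lambda hl: SummaryStats(half_life_days=hl, n_established=0,
                                     type_fractions={"K": 0, "T": 0, "G": 0},
                                     mutant_fraction=0.0)
        ens = summarize_ensemble([mk(10.0), mk(20.0)])
        assert ens.half_life_mean == 15.0
        assert ens.half_life_sem == pytest.approx(5.0)

    def test_sentinels_reported_as_fraction_reached(self):
        mk = lambda hl: SummaryStats(half_life_days=hl, n_established=0,
                                     type_fractions={"K": 0, "T": 0, "G": 0},
                                     mutant_fraction=0.0)
        ens = summarize_ensemble([mk(10.0), mk(math.inf), mk(14.0), mk(math.inf)])
        assert ens.fraction_half_life_reached == 0.5
        assert ens.half_life_mean == 12.0

    def test_sem_matches_bootstrap(self, rng):
        hls = rng.gamma(4.0, 2.0, size=100)
        mk = lambda hl: SummaryStats(half_life_days=float(hl), n_established=0,
                                     type_fractions={"K": 0, "T": 0, "G": 0},
                                     mutant_fraction=0.0)
        ens = summarize_ensemble([mk(h) for h in hls])
        boots = [rng.choice(hls, size=hls.size, replace=True).mean()
                 for _ in range(2000)]
        assert ens.half_life_sem == pytest.approx(np.std(boots), rel=0.2)


def test_lumped_and_simulator_agree_in_deterministic_limit(
        params, switching, modes, envs):
    """Single mutation type (K), all-ODE lineages, exact dilution: the
    detailed simulator's ancestral half-life matches the lumped model
    within 15%."""
    env = envs["D2Z0"]
    cfg = SimConfig(p_T=0.0, p_G=0.0, stochastic_size_threshold=0.0,
                    deterministic_resuspension=True, duration_days=8.0)
    sim = Simulator(params, switching, modes, cfg)
    _, stats = sim.run_replicate(env, seed=1, record_trajectory=False)
    fits = class_fitnesses(env, params, switching, modes)
    spec = MutationSpec(mu=cfg.mu_no_z, p_T=0.0, p_G=0.0)
    lumped = simulate_lumped(spec, fits, duration_days=8.0)
    hl_lumped = ancestral_half_life(lumped)
    assert stats.half_life_days == pytest.approx(hl_lumped, rel=0.15)
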