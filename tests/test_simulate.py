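import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecocline.simulate import (
    M1,
    M2,
    ConfigurationError,
    EffectTable,
    ExtinctionError,
    Genome,
    ParameterError,
    ScenarioSpec,
    desk_spec,
    draw_effect_table,
    fitness_vector,
    hgt_event,
    migrate_stepping_stone,
    mutate_population,
    reproduce_and_regulate,
    run_scenario,
    sample_hgt_donor,
    sample_hgt_start,
    trait_score,
)
from ecocline.snpmatrix import encode_binary


class TestMutatePopulation:
    def test_zero_rate_is_identity(self, rng):
        pop = [Genome.from_mutations({3: M1, 9: M2}) for _ in range(5)]
        out = mutate_population(pop, 0.0, 100, rng)
        assert all(a == b for a, b in zip(pop, out))

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ParameterError):
            mutate_population([Genome()], -1e-6, 100, rng)

    def test_mean_new_mutations_matches_per_genome_rate(self, rng):
        # rate 1e-6 on a 1 Mb genome: one expected mutation per genome
        pop = [Genome() for _ in range(10_000)]
        out = mutate_population(pop, 1e-6, 1_000_000, rng)
        mean = np.mean([g.n_mutations for g in out])
        se = np.sqrt(1.0 / len(pop))  # Poisson(1) mean over 1e4 genomes
        assert abs(mean - 1.0) < 3 * se

    def test_mutation_types_drawn_one_to_one(self, rng):
        pop = [Genome() for _ in range(2_000)]
        out = mutate_population(pop, 1e-3, 10_000, rng)
        types = np.concatenate([g.types for g in out])
        frac_m1 = (types == M1).mean()
        se = 0.5 / np.sqrt(types.size)
        assert abs(frac_m1 - 0.5) < 3 * se

    def test_new_mutation_replaces_resident(self, rng):
        # rate high enough that every site mutates many times; one site only
        pop = [Genome.from_mutations({0: M1})]
        out = mutate_population(pop, 50.0, 1, rng)[0]
        assert out.n_mutations == 1 and out.positions[0] == 0

    def test_mask_disables_mutation(self, rng):
        pop = [Genome(), Genome()]
        out = mutate_population(pop, 10.0, 100, rng, mask=[False, True])
        assert out[0].n_mutations == 0 and out[1].n_mutations > 0


class TestHgtEvent:
    def test_empty_tract_is_identity(self):
        r = Genome.from_mutations({5: M1})
        assert hgt_event(r, Genome.from_mutations({7: M2}), 0, 0) is r

    def test_self_copy_is_identity(self):
        r = Genome.from_mutations({5: M1})
        assert hgt_event(r, r, 0, 100) is r

    def test_interval_replacement(self):
        r = Genome.from_mutations({5: M1, 100: M2})
        d = Genome.from_mutations({100: M1, 900: M2})
        out = hgt_event(r, d, 50, 100)
        assert out.mutations == {5: M1, 100: M1}

    def test_idempotent_on_equal_tracts(self):
        r = Genome.from_mutations({5: M1, 60: M2})
        d = Genome.from_mutations({60: M2, 200: M1})
        once = hgt_event(r, d, 50, 20)
        twice = hgt_event(once, d, 50, 20)
        assert once == twice

    def test_disjoint_tracts_commute(self):
        r = Genome.from_mutations({5: M1, 60: M2, 150: M1})
        d = Genome.from_mutations({10: M2, 70: M1, 160: M2})
        ab = hgt_event(hgt_event(r, d, 0, 30), d, 140, 30)
        ba = hgt_event(hgt_event(r, d, 140, 30), d, 0, 30)
        assert ab == ba

    def test_truncation_without_genome_length(self):
        r = Genome.from_mutations({5: M1, 95: M2})
        d = Genome.from_mutations({2: M2, 96: M1})
        out = hgt_event(r, d, 90, 100)
        assert out.mutations == {5: M1, 96: M1}

    def test_wraparound_with_genome_length(self):
        r = Genome.from_mutations({5: M1, 95: M2})
        d = Genome.from_mutations({2: M2, 96: M1})
        # circular tract [90, 10): replaces both ends
        out = hgt_event(r, d, 90, 20, genome_length=100)
        assert out.mutations == {2: M2, 96: M1}


class TestSampleHgtStart:
    def test_zero_fraction_uniform(self, rng):
        from scipy import stats

        spec = ScenarioSpec(scenario="neutral", genome_length=10_000, generations=1)
        draws = np.array([sample_hgt_start(spec, rng) for _ in range(20_000)])
        counts, _ = np.histogram(draws, bins=10, range=(0, 10_000))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_hotspot_fraction_respected(self, rng):
        spec = ScenarioSpec(
            scenario="hotspot",
            genome_length=1_000_000,
            hotspot_positions=(250_000, 500_000, 750_000),
            hotspot_fraction=0.8,
            generations=1,
        )
        hot = set(spec.hotspot_positions)
        draws = [sample_hgt_start(spec, rng) for _ in range(10_000)]
        frac = np.mean([d in hot for d in draws])
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(frac - 0.8) < 3 * se

    def test_forced_single_hotspot(self, rng):
        spec = ScenarioSpec(
            scenario="hotspot",
            genome_length=1_000_000,
            hotspot_positions=(123_456,),
            hotspot_fraction=1.0,
            generations=1,
        )
        assert all(sample_hgt_start(spec, rng) == 123_456 for _ in range(100))

    def test_missing_hotspots_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec(scenario="hotspot", hotspot_fraction=0.5, generations=1)


class TestTraitScore:
    def test_empty_genome_scores_zero(self):
        assert trait_score(Genome(), EffectTable.uniform(100)) == 0.0

    def test_uniform_effects_count_difference(self):
        g = Genome.from_mutations({1: M1, 2: M1, 3: M1, 4: M2})
        assert trait_score(g, EffectTable.uniform(10)) == 2.0

    def test_weighted_effects(self):
        eff = EffectTable(10, [1.0] * 10)
        eff.coefficients[1] = 0.5
        eff.coefficients[2] = 2.0
        eff.coefficients[3] = 1.0
        g = Genome.from_mutations({1: M1, 2: M1, 3: M2})
        assert trait_score(g, eff) == pytest.approx(1.5)

    def test_uniform_matches_direct_count_on_random_genomes(self, rng):
        eff = EffectTable.uniform(1_000)
        for _ in range(100):
            k = int(rng.integers(0, 50))
            pos = rng.choice(1_000, size=k, replace=False)
            typ = rng.integers(M1, M2 + 1, size=k)
            g = Genome.from_mutations(dict(zip(pos.tolist(), typ.tolist())))
            expected = int((typ == M1).sum()) - int((typ == M2).sum())
            assert trait_score(g, eff) == expected


class TestFitnessVector:
    def test_all_equal_scores_give_exactly_two(self):
        assert np.all(fitness_vector([3.0] * 7, 1.0, 5, 1e-6) == 2.0)

    def test_hand_worked_example(self):
        # mean 10/3; deviation ratio of the two low scores is (1/2)^5
        f = fitness_vector([0.0, 0.0, 10.0], 1.0, 5, 1e-6)
        assert f[0] == pytest.approx(2.03125, abs=1e-4)
        assert f[1] == pytest.approx(2.03125, abs=1e-4)
        assert f[2] == pytest.approx(3.0, abs=1e-4)

    @given(
        st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=50),
        st.sampled_from([(1.0, 5), (0.5, 10)]),
    )
    def test_bounds(self, scores, amp_exp):
        # open upper bound in exact arithmetic; float rounding of
        # d/(d + eps) can reach it exactly for huge deviations
        amp, exp = amp_exp
        f = fitness_vector(scores, amp, exp, 1e-6)
        assert np.all(f >= 2.0) and np.all(f <= 2.0 + amp)

    def test_empty_scores_rejected(self):
        with pytest.raises(ParameterError):
            fitness_vector([], 1.0, 5, 1e-6)


class TestReproduceAndRegulate:
    def test_mean_offspring_near_lambda(self, rng):
        pop = [Genome() for _ in range(10_000)]
        _, counts = reproduce_and_regulate(
            pop, np.full(10_000, 2.0), 10**9, rng, return_counts=True
        )
        se = np.sqrt(2.0 / 10_000)
        assert abs(counts.mean() - 2.0) < 3 * se

    def test_extinction_raises(self, rng):
        with pytest.raises(ExtinctionError):
            reproduce_and_regulate([Genome()] * 5, np.zeros(5), 100, rng)

    def test_capacity_regulation_exact(self, rng):
        pop = [Genome() for _ in range(100)]
        out = reproduce_and_regulate(pop, np.full(100, 5.0), 100, rng)
        assert len(out) == 100

    def test_all_survive_below_capacity(self, rng):
        pop = [Genome() for _ in range(10)]
        out = reproduce_and_regulate(pop, np.full(10, 1.0), 10**6, rng)
        assert 0 < len(out) <= 10 * 20  # every offspring kept


class TestMigrateSteppingStone:
    def test_zero_migrants_identity(self, rng):
        demes = [[Genome(lineage_id=i)] * 3 for i in range(3)]
        out = migrate_stepping_stone(demes, 0, rng)
        assert [len(d) for d in out] == [3, 3, 3]

    def test_total_count_conserved(self, rng):
        demes = [
            [Genome(deme=d, lineage_id=d * 200 + i) for i in range(200)]
            for d in range(10)
        ]
        out = migrate_stepping_stone(demes, 10, rng)
        assert sum(len(d) for d in out) == 2_000
        ids = sorted(g.lineage_id for d in out for g in d)
        assert ids == list(range(2_000))

    def test_three_deme_exchange_counts(self, rng):
        demes = [
            [Genome(deme=d, lineage_id=d * 10 + i) for i in range(10)]
            for d in range(3)
        ]
        out = migrate_stepping_stone(demes, 1, rng)
        # end demes send/receive one; the middle deme sends 2 and receives 2
        assert [len(d) for d in out] == [10, 10, 10]
        origins = [[g.lineage_id // 10 for g in d] for d in out]
        assert sum(o != 0 for o in origins[0]) == 1
        assert sum(o != 1 for o in origins[1]) == 2
        assert sum(o != 2 for o in origins[2]) == 1

    def test_migrants_exceeding_deme_rejected(self, rng):
        demes = [[Genome()] * 2, [Genome()] * 2, [Genome()] * 2]
        with pytest.raises(ConfigurationError):
            migrate_stepping_stone(demes, 2, rng)  # middle needs 4 > 2


class TestDrawEffectTable:
    def test_near_degenerate_gamma_mean_one(self, rng):
        eff = draw_effect_table(10_000, 1e6, 1e-6, rng)
        assert abs(eff.coefficients.mean() - 1.0) < 1e-2
        assert eff.coefficients.std() < 1e-2

    def test_exponential_law_mean(self, rng):
        eff = draw_effect_table(1_000_000, 1.0, 1.0, rng)
        se = 1.0 / 1_000  # sd 1, one million sites
        assert abs(eff.coefficients.mean() - 1.0) < 3 * se

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(ParameterError):
            draw_effect_table(10, 0.0, 1.0, rng)
        with pytest.raises(ParameterError):
            draw_effect_table(10, 1.0, -1.0, rng)


def _tiny(scenario, **kw):
    base = dict(
        scenario=scenario,
        genome_length=10_000,
        pop_size=40,
        mutation_rate=1e-4,
        hgt_tract_length=300,
        generations=50,
        selection_start=26,
        seed=5,
    )
    base.update(kw)
    return ScenarioSpec(**base)


class TestRunScenario:
    def test_zero_generations_returns_initial_population(self):
        out = run_scenario(_tiny("neutral", generations=0))
        assert len(out.final_population) == 40
        assert all(g.n_mutations == 0 for g in out.final_population)
        assert np.all(out.trait_values == 0)

    def test_seed_determinism(self):
        a = run_scenario(_tiny("selective_uniform"))
        b = run_scenario(_tiny("selective_uniform"))
        assert all(x == y for x, y in zip(a.final_population, b.final_population))
        assert np.array_equal(a.trait_values, b.trait_values)
        assert a.generation_log.equals(b.generation_log)

    def test_every_individual_receives_hgt(self):
        out = run_scenario(_tiny("neutral", pop_size=1_000, generations=1))
        assert out.generation_log["hgt_recipients"].iloc[0] == 1_000

    def test_population_size_never_exceeds_capacity(self):
        out = run_scenario(_tiny("neutral"))
        assert np.all(out.generation_log["pop_size"] <= 40)

    def test_mutation_het_p1_lineages_stay_unmutated(self):
        out = run_scenario(_tiny("mutation_het", hgt_events_per_gen=0))
        p1 = [g for g in out.final_population if g.lineage_id % 2 == 0]
        p2 = [g for g in out.final_population if g.lineage_id % 2 == 1]
        assert p1 and p2
        assert all(g.n_mutations == 0 for g in p1)
        assert any(g.n_mutations > 0 for g in p2)

    def test_stepping_stone_keeps_deme_sizes(self):
        out = run_scenario(
            _tiny("stepping_stone", pop_size=40, n_demes=4, migrants_per_gen=2)
        )
        demes = np.array([g.deme for g in out.final_population])
        assert np.array_equal(np.bincount(demes, minlength=4), [10, 10, 10, 10])

    def test_trait_values_match_encoded_population(self):
        out = run_scenario(_tiny("selective_uniform"))
        # recompute the trait from scratch for a few genomes
        from ecocline.simulate import trait_score

        for g, t in list(zip(out.final_population, out.trait_values))[:10]:
            assert trait_score(g, out.effects) == pytest.approx(t)


def test_sample_hgt_donor_excludes_recipient(rng):
    draws = {sample_hgt_donor(5, 2, rng) for _ in range(200)}
    assert 2 not in draws and draws <= {0, 1, 3, 4}


def test_desk_preset_preserves_per_genome_rates():
    spec = desk_spec("selective_uniform")
    assert spec.mutation_rate * spec.genome_length == pytest.approx(1.0)
    assert spec.hgt_events_per_gen == 1
    full_scale_ratio = 20_000 / 1_000_000
    assert spec.hgt_tract_length / spec.genome_length == pytest.approx(full_scale_ratio)
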