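"""Genetic algorithm: fitness scaling, operators, elitism, full runs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import curvsense as cv
from curvsense.evolve import (
    cosine_window, evaluate_population, random_population, select_parents, step,
)
from curvsense.surrogate import SurrogateBackend

CFG = cv.GAConfig()


class TestFitnessScaling:
    def test_surface_depth_keeps_full_score(self):
        assert cv.scale_fitness(-10.0, CFG.b_tensionless, CFG.b_stretched, CFG) == pytest.approx(-10.0)

    @pytest.mark.parametrize("d_t, d_s", [(0.0, 0.0), (3.8, 3.58), (5.0, 5.0)])
    def test_soluble_or_transmembrane_scores_zero(self, d_t, d_s):
        assert cv.scale_fitness(-10.0, d_t, d_s, CFG) == pytest.approx(0.0)

    def test_half_depth_halves_the_score(self):
        assert cv.scale_fitness(
            -10.0, CFG.b_tensionless / 2, CFG.b_stretched / 2, CFG
        ) == pytest.approx(-5.0)

    def test_worst_condition_wins(self):
        # stretched condition soluble -> factor 0 regardless of the other
        assert cv.scale_fitness(-10.0, CFG.b_tensionless, 10.0, CFG) == 0.0

    @given(st.floats(-1.0, 6.0))
    @settings(deadline=None)
    def test_window_bounded_and_continuous(self, d):
        b = 1.90
        c = cosine_window(d, b)
        assert 0.0 <= c <= 1.0
        assert abs(cosine_window(d + 1e-9, b) - c) < 1e-6  # continuity
        assert cosine_window(b, b) == pytest.approx(1.0)


class TestCrossover:
    def test_tail_swap(self):
        a, b = cv.Peptide("AAAAAA"), cv.Peptide("WWWWWW")
        c1, c2 = cv.crossover(a, b, i=2)
        assert (c1.sequence, c2.sequence) == ("AAWWWW", "WWAAAA")

    def test_identical_parents_identical_children(self):
        p = cv.Peptide("AWAWAW")
        c1, c2 = cv.crossover(p, p, i=3)
        assert c1.sequence == c2.sequence == p.sequence

    def test_positionwise_residues_are_permuted_parent_pairs(self):
        rng = np.random.default_rng(11)
        letters = list("ALMKQEWSYF")
        for _ in range(20):
            s1 = "".join(rng.choice(letters, size=12))
            s2 = "".join(rng.choice(letters, size=12))
            c1, c2 = cv.crossover(cv.Peptide(s1), cv.Peptide(s2), rng=rng)
            for i in range(12):
                assert sorted((c1.sequence[i], c2.sequence[i])) == sorted((s1[i], s2[i]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            cv.crossover(cv.Peptide("AAA"), cv.Peptide("AAAA"), i=1)


class TestMutate:
    def test_zero_rate_is_identity(self):
        p = cv.Peptide("ALMKQEWSYF")
        rng = np.random.default_rng(0)
        assert cv.mutate(p, 0.0, rng).sequence == p.sequence

    def test_unit_rate_changes_every_position(self):
        p = cv.Peptide("A" * 24, cv.Alphabet.reduced10)
        rng = np.random.default_rng(0)
        mutant = cv.mutate(p, 1.0, rng)
        assert sum(a != b for a, b in zip(p.sequence, mutant.sequence)) == 24

    def test_expected_one_point_mutation_per_child(self):
        # P_mut = 1/L with L = 24 gives on average one substitution
        p = cv.Peptide("ALMKQEWSYFALMKQEWSYFALMK", cv.Alphabet.reduced10)
        rng = np.random.default_rng(123)
        dist = [
            sum(a != b for a, b in zip(p.sequence, cv.mutate(p, 1 / 24, rng).sequence))
            for _ in range(10_000)
        ]
        assert np.mean(dist) == pytest.approx(1.0, abs=0.03)

    def test_respects_restricted_letters(self):
        p = cv.Peptide("AAAAA")
        rng = np.random.default_rng(4)
        mutant = cv.mutate(p, 1.0, rng, letters="AWE")
        assert set(mutant.sequence) <= set("AWE")


class TestSelection:
    def _pop(self, fitnesses):
        pop = cv.Population(members=[])
        for i, f in enumerate(fitnesses):
            ind = cv.Individual(cv.Peptide("A" * 5), fitness_history=[f])
            pop.members.append(pop.register(ind))
        return pop

    def test_selects_k_lowest(self):
        pop = self._pop([3.0, -1.0, -5.0, 2.0])
        assert [i.fitness for i in select_parents(pop, 2)] == [-5.0, -1.0]

    def test_tie_break_by_birth_order(self):
        pop = self._pop([0.0, 0.0, 0.0])
        assert [i.birth_order for i in select_parents(pop, 2)] == [0, 1]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(9)
        fits = rng.normal(size=144)
        pop = self._pop(list(fits))
        expect = sorted(fits)[:36]
        got = [i.fitness for i in select_parents(pop, 36)]
        assert np.allclose(got, expect)

    def test_empty_population_rejected(self):
        with pytest.raises(RuntimeError):
            select_parents(cv.Population(members=[]), 1)


def _small_cfg(seed=0, gens=10):
    return cv.GAConfig(
        population_size=24, parent_pool=6, length=8, max_generations=gens, seed=seed
    )


class TestStepAndRun:
    def test_elite_sequence_survives(self):
        cfg = _small_cfg()
        backend = SurrogateBackend(config=cfg)
        rng = np.random.default_rng(cfg.seed)
        pop = random_population(cfg, rng)
        evaluate_population(pop, backend, cfg)
        best = pop.best().sequence
        nxt = step(pop, backend, cfg, rng)
        assert best in {m.sequence for m in nxt.members}

    def test_population_size_and_alphabet_conserved(self):
        cfg = _small_cfg(seed=5)
        backend = SurrogateBackend(config=cfg)
        rng = np.random.default_rng(cfg.seed)
        pop = random_population(cfg, rng)
        evaluate_population(pop, backend, cfg)
        for _ in range(10):
            pop = step(pop, backend, cfg, rng)
            assert len(pop) == cfg.population_size
            assert all(
                set(m.sequence) <= set(cfg.letters) and len(m.peptide) == cfg.length
                for m in pop.members
            )

    def test_best_fitness_monotone_under_deterministic_backend(self):
        cfg = _small_cfg(seed=1, gens=15)
        trace = cv.run(cfg, SurrogateBackend(config=cfg))
        best = trace.best_fitness
        assert all(b1 >= b2 - 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_same_seed_same_trace(self):
        cfg = _small_cfg(seed=42)
        backend = SurrogateBackend(config=cfg)
        t1, t2 = cv.run(cfg, backend), cv.run(cfg, backend)
        assert t1.best_sequences == t2.best_sequences
        assert t1.best_fitness == t2.best_fitness
        assert t1.mean_fitness == t2.mean_fitness

    def test_zero_generations_returns_evaluated_initial_population(self):
        cfg = cv.GAConfig(population_size=12, parent_pool=4, length=6,
                          max_generations=0, seed=2)
        trace = cv.run(cfg, SurrogateBackend(config=cfg))
        assert len(trace.best_fitness) == 1
        assert all(m.n_evals == 1 for m in trace.final_population.members)

    def test_mean_fitness_improves_at_scaled_down_defaults(self):
        cfg = cv.GAConfig(population_size=48, parent_pool=12, max_generations=30, seed=3)
        trace = cv.run(cfg, SurrogateBackend(config=cfg))
        assert trace.mean_fitness[-1] < trace.mean_fitness[0]

    def test_failed_evaluation_scores_zero_and_run_continues(self):
        class FlakyBackend:
            def __init__(self, inner):
                self.inner, self.n = inner, 0

            def evaluate(self, seq):
                self.n += 1
                if self.n % 7 == 0:
                    raise RuntimeError("backend crash")
                return self.inner.evaluate(seq)

        cfg = _small_cfg(seed=8, gens=3)
        trace = cv.run(cfg, FlakyBackend(SurrogateBackend(config=cfg)))
        assert len(trace.best_fitness) == 4  # initial + 3 generations

    def test_rerun_elites_accumulate_evaluations(self):
        cfg = _small_cfg(seed=6, gens=12)
        trace = cv.run(cfg, SurrogateBackend(config=cfg))
        assert max(m.n_evals for m in trace.final_population.members) > cfg.rerun_elite_threshold
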