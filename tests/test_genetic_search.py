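"""Population dynamics: selection, elitism, stagnation recovery, accounting."""

import math
import random
from collections import Counter

import numpy as np
import pytest

from gwfold import (
    Conformation,
    ContactEnergyMatrix,
    EvaluationCounter,
    GAConfig,
    Individual,
    chain_growth_init,
    elitist_replace,
    evaluate_energy,
    evolve_generation,
    random_walk_recover,
    run_search,
    select_operator,
    threshold_for_length,
)
from gwfold.genetic_search import DEFAULT_OPERATOR_PROBABILITIES, SearchState
from gwfold.fcc_lattice import decode_conformation, validate
from gwfold import move_operators as mo


@pytest.fixture()
def micro_state(bm, rng):
    seq = "MKKYTCTV"
    counter = EvaluationCounter()
    pop = []
    for _ in range(4):
        conf = chain_growth_init(8, rng)
        coords = conf.decode()
        pop.append(Individual(conf, coords,
                              evaluate_energy(coords, seq, bm)))
    best = min(pop, key=lambda i: i.energy).clone()
    return seq, SearchState(population=pop, best_global=best,
                            best_current=best, counter=counter)


class TestSelectOperator:
    def test_degenerate_distribution(self, rng):
        assert select_operator({"pull": 1.0}, rng) == "pull"

    def test_frequencies_match_distribution(self):
        rng = random.Random(1)
        n = 10 ** 6
        draws = Counter(select_operator(DEFAULT_OPERATOR_PROBABILITIES, rng)
                        for _ in range(n))
        for tag, p in DEFAULT_OPERATOR_PROBABILITIES.items():
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(draws[tag] - n * p) < 3 * sigma

    def test_fixed_seed_gives_identical_draws(self):
        a = [select_operator(DEFAULT_OPERATOR_PROBABILITIES, random.Random(7))
             for _ in range(5)]
        b = [select_operator(DEFAULT_OPERATOR_PROBABILITIES, random.Random(7))
             for _ in range(5)]
        assert a == b

    def test_malformed_distribution_rejected(self, rng):
        with pytest.raises(ValueError):
            select_operator({"pull": 0.7}, rng)


class TestElitistReplace:
    def test_strictly_better_child_survives(self):
        p = Individual(Conformation((1,)), [(0, 0, 0), (1, 1, 0)], -5.0)
        c = Individual(Conformation((3,)), [(0, 0, 0), (-1, 1, 0)], -10.0)
        assert elitist_replace(p, c) is c

    def test_tie_keeps_parent(self):
        p = Individual(Conformation((1,)), [(0, 0, 0), (1, 1, 0)], -5.0)
        c = Individual(Conformation((3,)), [(0, 0, 0), (-1, 1, 0)], -5.0)
        assert elitist_replace(p, c) is p


class TestEvolveGeneration:
    def test_identical_population_under_crossover_is_unchanged(self, bm, rng):
        seq = "MKKYTCTV"
        conf = chain_growth_init(8, rng)
        coords = conf.decode()
        e = evaluate_energy(coords, seq, bm)
        pop = [Individual(conf, list(coords), e) for _ in range(4)]
        best = pop[0].clone()
        state = SearchState(population=pop, best_global=best,
                            best_current=best)
        cfg = GAConfig(population_size=4, max_generations=1,
                       operator_probabilities={"crossover": 1.0}).validated()
        evolve_generation(state, cfg, seq, bm, rng)
        assert all(ind.conformation == conf for ind in state.population)
        assert state.tracking_non_improvement == 1

    def test_population_slot_energies_never_worsen(self, bm, micro_state, rng):
        seq, state = micro_state
        cfg = GAConfig(population_size=4, max_generations=1).validated()
        for _ in range(30):
            before = [ind.energy for ind in state.population]
            evolve_generation(state, cfg, seq, bm, rng)
            after = [ind.energy for ind in state.population]
            assert all(a <= b + 1e-12 for a, b in zip(after, before))

    def test_best_global_monotone_and_tracking_resets(self, bm, micro_state,
                                                      rng):
        seq, state = micro_state
        cfg = GAConfig(population_size=4, max_generations=1).validated()
        best_history = [state.best_global.energy]
        for _ in range(40):
            prev_tracking = state.tracking_non_improvement
            evolve_generation(state, cfg, seq, bm, rng)
            best_history.append(state.best_global.energy)
            if best_history[-1] < best_history[-2]:
                assert state.tracking_non_improvement == 0
            else:
                assert state.tracking_non_improvement == prev_tracking + 1
        assert best_history == sorted(best_history, reverse=True)


class TestRandomWalkRecover:
    def test_population_stays_valid_and_best_global_untouched(self, bm,
                                                              micro_state,
                                                              rng):
        seq, state = micro_state
        cfg = GAConfig(population_size=4, max_generations=1).validated()
        archived = state.best_global
        random_walk_recover(state, cfg, seq, bm, rng)
        assert state.best_global is archived
        assert state.tracking_non_improvement == 0
        for ind in state.population:
            assert validate(ind.conformation)
            assert ind.energy == pytest.approx(
                evaluate_energy(ind.coords, seq, bm))

    def test_shuffle_parameter_grows_only_after_barren_recovery(self, bm,
                                                                micro_state,
                                                                rng):
        seq, state = micro_state
        cfg = GAConfig(population_size=4, max_generations=1).validated()
        assert state.shuffle_parameter == 1
        random_walk_recover(state, cfg, seq, bm, rng)
        assert state.shuffle_parameter == 1  # first recovery never escalates
        random_walk_recover(state, cfg, seq, bm, rng)
        assert state.shuffle_parameter == 2  # no improvement in between
        state.improved_since_recovery = True
        random_walk_recover(state, cfg, seq, bm, rng)
        assert state.shuffle_parameter == 2

    def test_larger_shuffle_moves_population_further(self, bm):
        """Structural distance after recovery grows with the parameter."""
        seq = "MKKYTCTVCGYIYNPEDGDP"

        def mean_distance(shuffle):
            dists = []
            for seed in range(8):
                rng = random.Random(seed)
                pop = []
                for _ in range(4):
                    conf = chain_growth_init(20, rng)
                    coords = conf.decode()
                    pop.append(Individual(conf, coords,
                                          evaluate_energy(coords, seq, bm)))
                best = pop[0].clone()
                state = SearchState(population=pop, best_global=best,
                                    best_current=best,
                                    shuffle_parameter=shuffle,
                                    improved_since_recovery=True)
                before = [ind.conformation.directions for ind in pop]
                cfg = GAConfig(population_size=4,
                               max_generations=1).validated()
                random_walk_recover(state, cfg, seq, bm, rng)
                for prev, ind in zip(before, state.population):
                    diff = sum(a != b for a, b in
                               zip(prev, ind.conformation.directions))
                    dists.append(diff / len(prev))
            return np.mean(dists)

        assert mean_distance(2) > mean_distance(1)


class TestRunSearch:
    def test_zero_generations_returns_best_of_initial_population(self, bm):
        seq = "MKKYTCTVCGYIYNPEDGDP"
        cfg = GAConfig(population_size=6, max_generations=0, seed=3)
        stats = run_search(seq, cfg, bm)
        assert stats.generations == 0
        assert stats.evaluation_count == 6
        assert stats.best_bm_energy == stats.initial_bm_energy
        assert validate(stats.best_conformation)

    def test_fixed_seed_reproduces_the_run(self, bm):
        seq = "MKKYTCTVCGYIYNPEDGDP"
        cfg = GAConfig(population_size=6, max_generations=25, seed=9)
        a = run_search(seq, cfg, bm)
        b = run_search(seq, cfg, bm)
        assert a.best_conformation == b.best_conformation
        assert a.best_energy == b.best_energy
        assert a.evaluation_count == b.evaluation_count
        assert [r[:5] for r in a.trajectory] == [r[:5] for r in b.trajectory]

    def test_trajectory_best_energy_non_increasing(self, bm):
        seq = "MKKYTCTVCGYIYNPEDGDP"
        stats = run_search(seq, GAConfig(population_size=6,
                                         max_generations=40, seed=2), bm)
        energies = [r.best_energy for r in stats.trajectory]
        assert energies == sorted(energies, reverse=True)
        evals = [r.evaluation_count for r in stats.trajectory]
        assert evals == sorted(evals)

    def test_homopolymer_runs_improve_over_random_start(self, bm):
        """Short searches on a sticky homopolymer beat their own start."""
        ones = ContactEnergyMatrix(-np.ones((20, 20)))
        improved = 0
        for seed in range(20):
            cfg = GAConfig(population_size=8, max_generations=60, seed=seed,
                           guidance="BM", threshold_value=20)
            stats = run_search("A" * 20, cfg, ones)
            if stats.best_bm_energy < stats.initial_bm_energy:
                improved += 1
        assert improved >= 19  # >= 95% of seeds

    def test_guidance_gw_with_single_group_equals_bm_run(self, bm):
        from gwfold import GroupScheme
        seq = "MKKYTCTVCGYIYNPEDGDP"
        a = run_search(seq, GAConfig(population_size=5, max_generations=15,
                                     seed=4, guidance="GW"), bm,
                       scheme=GroupScheme.single_group())
        b = run_search(seq, GAConfig(population_size=5, max_generations=15,
                                     seed=4, guidance="BM"), bm)
        assert a.best_conformation == b.best_conformation
        assert a.best_energy == pytest.approx(b.best_energy)

    def test_non_exhaustive_variant_terminates_with_valid_output(self, bm):
        seq = "MKKYTCTVCGYIYNPEDGDP"
        cfg = GAConfig(population_size=6, max_generations=80, seed=6,
                       exhaustive=False)
        stats = run_search(seq, cfg, bm)
        assert validate(stats.best_conformation)
        assert stats.best_bm_energy <= stats.initial_bm_energy

    def test_stagnation_triggers_recovery(self, bm):
        seq = "MKKYTCTV"
        cfg = GAConfig(population_size=4, max_generations=120, seed=1,
                       threshold_value=5)
        stats = run_search(seq, cfg, bm)
        assert stats.recoveries >= 1

    def test_unsatisfiable_config_rejected_before_work(self, bm):
        with pytest.raises(ValueError):
            run_search("MKKY", GAConfig(population_size=1,
                                        max_generations=1), bm)
        with pytest.raises(ValueError):
            run_search("MKKY", GAConfig(), bm)  # no stopping budget at all
        with pytest.raises(ValueError):
            run_search("MKKY", GAConfig(max_generations=1,
                                        guidance="XX"), bm)

    def test_evaluation_budget_stops_the_run(self, bm):
        seq = "MKKYTCTVCGYIYNPEDGDP"
        cfg = GAConfig(population_size=6, max_evaluations=2000, seed=8)
        stats = run_search(seq, cfg, bm)
        assert stats.evaluation_count >= 2000
        # overshoot bounded by one generation of candidates
        assert stats.evaluation_count < 2000 + 6 * 20 * 30


class TestEvaluationAccounting:
    def test_counter_matches_call_interception_audit(self, bm, monkeypatch):
        """Every scored candidate ticks the counter exactly once."""
        calls = {"n": 0}
        real_full, real_delta = mo.score_full, mo.score_delta

        def audited_full(*args, **kwargs):
            calls["n"] += 1
            return real_full(*args, **kwargs)

        def audited_delta(*args, **kwargs):
            calls["n"] += 1
            return real_delta(*args, **kwargs)

        monkeypatch.setattr(mo, "score_full", audited_full)
        monkeypatch.setattr(mo, "score_delta", audited_delta)
        import gwfold.genetic_search as gs
        monkeypatch.setattr(gs, "score_full", audited_full)

        seq = "MKKYTCTVCGYIYNPEDGDP"
        cfg = GAConfig(population_size=5, max_generations=30, seed=12,
                       threshold_value=5)
        stats = run_search(seq, cfg, bm)
        assert stats.evaluation_count == calls["n"]

    def test_exhaustive_pull_ticks_once_per_feasible_candidate(self, bm, rng):
        seq = "MKKYTCTV"
        conf = chain_growth_init(8, rng)
        coords = conf.decode()
        e0 = evaluate_energy(coords, seq, bm)
        counter = EvaluationCounter()
        r = mo.exhaustive_apply("pull", coords, e0, seq, bm, rng,
                                counter=counter)
        assert counter.count == r.candidates

    def test_counter_tick_increments(self):
        c = EvaluationCounter()
        c.tick()
        c.tick(3)
        assert c.count == 4


class TestThresholdTable:
    @pytest.mark.parametrize("n, thr", [
        (54, 50), (58, 50), (61, 50), (64, 45), (69, 45), (74, 40),
        (90, 35), (108, 30), (120, 25), (142, 20), (160, 15), (279, 15),
        (40, 50), (300, 15), (100, 35),
    ])
    def test_step_lookup(self, n, thr):
        assert threshold_for_length(n) == thr
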