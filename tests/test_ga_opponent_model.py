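import numpy as np
import pytest

from anfga.fuzzy_preference import (
    ConfigurationError,
    IssueDomain,
    PreferenceProfile,
    TrapezoidMembership,
    aggregate_satisfaction,
)
from anfga.ga_opponent_model import (
    CandidateProfile,
    ConcessionLedger,
    GAParams,
    concession_weights,
    crossover,
    evolve,
    fitness,
    init_population,
    mutate,
    population_fitness,
    refine_weights,
    select,
)


def _profile(n=2):
    return PreferenceProfile(
        np.full(n, 1.0 / n),
        [TrapezoidMembership(0.0, 0.3, 0.6, 1.0) for _ in range(n)],
    )


def _domains(n=2):
    return [IssueDomain(f"i{k}", 0.0, 1.0, 0.1) for k in range(n)]


def _seed_for_branch(want_rule_a: bool) -> int:
    """Find a seed whose first uniform draw lands in the wanted crossover
    branch (rule (a) iff the draw is < 0.5)."""
    for s in range(1000):
        if (np.random.default_rng(s).random() < 0.5) == want_rule_a:
            return s
    raise AssertionError("unreachable")


class TestGAParams:
    def test_elite_count(self):
        assert GAParams(population_size=100, elite_rate=0.1).elite_count == 10

    def test_invalid_elite(self):
        with pytest.raises(ConfigurationError):
            GAParams(population_size=2, elite_rate=0.9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 1},
            {"max_iteration": 0},
            {"mutation_rate": 1.5},
            {"mutation_mode": "bogus"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigurationError):
            GAParams(**kwargs)


class TestInitPopulation:
    def test_invariants(self, rng):
        pop = init_population(_profile(3), _domains(3), GAParams(population_size=100), rng)
        assert len(pop) == 100
        for ind in pop:
            assert ind.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(ind.a <= ind.b) and np.all(ind.b <= ind.c) and np.all(ind.c <= ind.d)
            assert np.all(ind.b >= 0.0) and np.all(ind.c <= 1.0)

    def test_single_issue_weight_forced(self, rng):
        pop = init_population(_profile(1), _domains(1), GAParams(population_size=10), rng)
        for ind in pop:
            assert ind.weights[0] == pytest.approx(1.0)

    def test_seed_determinism(self):
        p1 = init_population(_profile(), _domains(), GAParams(), np.random.default_rng(5))
        p2 = init_population(_profile(), _domains(), GAParams(), np.random.default_rng(5))
        for i1, i2 in zip(p1, p2):
            np.testing.assert_array_equal(i1.weights, i2.weights)
            np.testing.assert_array_equal(i1.b, i2.b)
            np.testing.assert_array_equal(i1.c, i2.c)

    def test_ad_copied_from_own_profile(self, rng):
        own = PreferenceProfile(
            [0.5, 0.5],
            [
                TrapezoidMembership(0.1, 0.3, 0.4, 0.7),
                TrapezoidMembership(0.2, 0.5, 0.6, 0.9),
            ],
        )
        pop = init_population(own, _domains(), GAParams(population_size=5), rng)
        for ind in pop:
            np.testing.assert_array_equal(ind.a, [0.1, 0.2])
            np.testing.assert_array_equal(ind.d, [0.7, 0.9])


class TestFitness:
    def test_single_round_product(self):
        """f = psi_own(A) * psi_cand(B) for one exchanged pair."""
        own = _profile(1)
        cand = CandidateProfile(
            np.array([1.0]), np.array([0.3]), np.array([0.6]),
            np.array([0.0]), np.array([1.0]),
        )
        a_offer = (0.15,)  # own membership: 1 - ((0.15-0.3)/0.3)^2 = 0.75
        b_offer = (0.8,)  # candidate: 1 - ((0.8-0.6)/(0.6-1.0))^2 = 0.75
        expected = aggregate_satisfaction(own, a_offer) * cand.satisfaction(b_offer)
        assert fitness(cand, own, [(a_offer, b_offer)]) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.5625, abs=1e-12)

    def test_plateau_candidate_gives_mean_own(self):
        own = _profile(1)
        cand = CandidateProfile(
            np.array([1.0]), np.array([0.0]), np.array([1.0]),
            np.array([0.0]), np.array([1.0]),
        )
        history = [((0.4,), (0.9,)), ((0.5,), (0.2,))]
        expected = np.mean(
            [aggregate_satisfaction(own, a) for a, _ in history]
        )
        # plateau covers every b -> psi_cand = 1... except boundary x>=d is 0
        assert fitness(cand, own, history) == pytest.approx(expected, abs=1e-12)

    def test_two_round_average(self):
        own = _profile(1)
        cand = CandidateProfile(
            np.array([1.0]), np.array([0.3]), np.array([0.6]),
            np.array([0.0]), np.array([1.0]),
        )
        history = [((0.4,), (0.5,)), ((0.35,), (0.8,))]
        expected = np.mean(
            [
                aggregate_satisfaction(own, a) * cand.satisfaction(b)
                for a, b in history
            ]
        )
        assert fitness(cand, own, history) == pytest.approx(expected, abs=1e-12)

    def test_empty_history_rejected(self):
        cand = CandidateProfile(
            np.array([1.0]), np.array([0.3]), np.array([0.6]),
            np.array([0.0]), np.array([1.0]),
        )
        with pytest.raises(ValueError):
            fitness(cand, _profile(1), [])

    def test_population_fitness_matches_scalar(self, rng):
        own = _profile(2)
        pop = init_population(own, _domains(), GAParams(population_size=8), rng)
        history = [((0.2, 0.4), (0.7, 0.6)), ((0.3, 0.3), (0.6, 0.7))]
        fvec = population_fitness(pop, own, history)
        for ind, f in zip(pop, fvec):
            assert f == pytest.approx(fitness(ind, own, history), abs=1e-12)


class TestSelect:
    def _pop2(self, rng):
        return init_population(_profile(1), _domains(1), GAParams(population_size=2), rng)

    def test_roulette_frequencies(self, rng):
        """Empirical selection frequencies for fitnesses (1, 3) within +-0.02
        of the (0.25, 0.75) theory at 10^4 draws."""
        pop = self._pop2(rng)
        params = GAParams(population_size=2, elite_rate=0.0)
        fitnesses = np.array([1.0, 3.0])
        counts = np.zeros(2)
        draws = 0
        for _ in range(5000):
            chosen = select(pop, fitnesses, params, rng)
            for ind in chosen:
                counts[0 if ind is pop[0] else 1] += 1
                draws += 1
        freq = counts / draws
        assert draws == 10000
        assert freq[0] == pytest.approx(0.25, abs=0.02)
        assert freq[1] == pytest.approx(0.75, abs=0.02)

    def test_uniform_fitness_uniform_probability(self, rng):
        pop = init_population(_profile(1), _domains(1), GAParams(population_size=4), rng)
        params = GAParams(population_size=4, elite_rate=0.0)
        counts = np.zeros(4)
        for _ in range(2500):
            for ind in select(pop, np.ones(4), params, rng):
                counts[pop.index(ind)] += 1
        np.testing.assert_allclose(counts / counts.sum(), 0.25, atol=0.02)

    def test_elitism_keeps_argmax(self, rng):
        pop = init_population(_profile(1), _domains(1), GAParams(population_size=4), rng)
        params = GAParams(population_size=4, elite_rate=0.25)
        fitnesses = np.array([0.1, 0.9, 0.3, 0.2])
        for _ in range(20):
            chosen = select(pop, fitnesses, params, rng)
            assert chosen[0] is pop[1]

    def test_all_zero_fitness_uniform_fallback(self, rng):
        pop = init_population(_profile(1), _domains(1), GAParams(population_size=3), rng)
        params = GAParams(population_size=3, elite_rate=0.0)
        chosen = select(pop, np.zeros(3), params, rng)
        assert len(chosen) == 3


class TestCrossover:
    def test_identical_parents(self, rng):
        p = init_population(_profile(2), _domains(), GAParams(), rng)[0]
        for seed in range(10):
            child = crossover(p, p.copy(), np.random.default_rng(seed))
            np.testing.assert_allclose(child.weights, p.weights, atol=1e-12)
            np.testing.assert_allclose(child.b, p.b, atol=1e-12)
            np.testing.assert_allclose(child.c, p.c, atol=1e-12)

    def test_mean_rule_weights(self):
        a = np.zeros(2)
        d = np.ones(2)
        p1 = CandidateProfile(np.array([0.2, 0.8]), a + 0.1, a + 0.5, a, d)
        p2 = CandidateProfile(np.array([0.4, 0.6]), a + 0.3, a + 0.7, a, d)
        seed = _seed_for_branch(want_rule_a=False)
        child = crossover(p1, p2, np.random.default_rng(seed))
        np.testing.assert_allclose(child.weights, [0.3, 0.7], atol=1e-12)
        np.testing.assert_allclose(child.b, [0.2, 0.2], atol=1e-12)

    def test_mean_rule_breakpoints(self):
        a = np.zeros(1)
        d = np.full(1, 10.0)
        p1 = CandidateProfile(np.array([1.0]), np.array([3.0]), np.array([5.0]), a, d)
        p2 = CandidateProfile(np.array([1.0]), np.array([4.0]), np.array([6.0]), a, d)
        seed = _seed_for_branch(want_rule_a=False)
        child = crossover(p1, p2, np.random.default_rng(seed))
        assert child.b[0] == pytest.approx(3.5)
        assert child.c[0] == pytest.approx(5.5)

    def test_copy_rule_takes_whole_triples(self):
        a = np.zeros(2)
        d = np.ones(2)
        p1 = CandidateProfile(np.array([0.2, 0.8]), a + 0.1, a + 0.4, a, d)
        p2 = CandidateProfile(np.array([0.6, 0.4]), a + 0.2, a + 0.6, a, d)
        seed = _seed_for_branch(want_rule_a=True)
        child = crossover(p1, p2, np.random.default_rng(seed))
        # per issue, (w, b, c) comes from one parent before renormalization
        for i in range(2):
            src = p1 if child.b[i] == p1.b[i] else p2
            assert child.b[i] == src.b[i]
            assert child.c[i] == src.c[i]

    def test_invariants_preserved(self, rng):
        pop = init_population(_profile(3), _domains(3), GAParams(), rng)
        for _ in range(50):
            i, j = rng.integers(len(pop), size=2)
            child = crossover(pop[i], pop[j], rng)
            child.validate()


class TestMutate:
    def test_zero_rate_unchanged(self, rng):
        p = init_population(_profile(2), _domains(), GAParams(), rng)[0]
        child = mutate(p, GAParams(mutation_rate=0.0), rng)
        assert child is p

    def test_rate_one_single_issue(self, rng):
        p = init_population(_profile(1), _domains(1), GAParams(), rng)[0]
        child = mutate(p, GAParams(mutation_rate=1.0), rng)
        assert child.weights[0] == pytest.approx(1.0)
        assert 0.0 <= child.b[0] <= child.c[0] <= 1.0

    def test_invariants_preserved(self, rng):
        pop = init_population(_profile(4), _domains(4), GAParams(), rng)
        for ind in pop:
            for mode in ("single_issue", "per_gene"):
                child = mutate(ind, GAParams(mutation_rate=0.8, mutation_mode=mode), rng)
                child.validate()


class TestEvolve:
    def test_minimal_loop(self, rng):
        own = _profile(2)
        history = [((0.3, 0.4), (0.6, 0.7))]
        best = evolve(own, _domains(), history,
                      GAParams(population_size=2, max_iteration=1, elite_rate=0.0), rng)
        best.validate()

    def test_trace_non_decreasing(self, rng):
        own = _profile(3)
        history = [((0.3, 0.4, 0.2), (0.6, 0.7, 0.8)), ((0.35, 0.3, 0.25), (0.55, 0.6, 0.7))]
        trace = []
        evolve(own, _domains(3), history,
               GAParams(population_size=30, max_iteration=50), rng, trace=trace)
        assert len(trace) == 50
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_seed_determinism(self):
        own = _profile(2)
        history = [((0.3, 0.4), (0.6, 0.7))]
        params = GAParams(population_size=10, max_iteration=5)
        b1 = evolve(own, _domains(), history, params, np.random.default_rng(3))
        b2 = evolve(own, _domains(), history, params, np.random.default_rng(3))
        np.testing.assert_array_equal(b1.weights, b2.weights)
        np.testing.assert_array_equal(b1.b, b2.b)

    def test_beats_random_profile(self):
        """Monte-Carlo oracle: the evolved candidate's fitness beats a
        uniform-random candidate's in >= 95% of seeded runs."""
        own = PreferenceProfile(
            [0.4, 0.6],
            [
                TrapezoidMembership(0.0, 0.2, 0.5, 1.0),
                TrapezoidMembership(0.0, 0.4, 0.7, 1.0),
            ],
        )
        opp = PreferenceProfile(
            [0.7, 0.3],
            [
                TrapezoidMembership(0.0, 0.5, 0.8, 1.0),
                TrapezoidMembership(0.0, 0.1, 0.4, 1.0),
            ],
        )
        doms = _domains(2)
        rng = np.random.default_rng(0)
        # 10 exchanged pairs: own offers near own plateau, opponent offers
        # drifting from the opponent's plateau toward the middle
        history = [
            (
                (0.3 + 0.02 * k, 0.5 - 0.01 * k),
                (0.65 - 0.02 * k, 0.25 + 0.02 * k),
            )
            for k in range(10)
        ]
        wins = 0
        n_runs = 100
        params = GAParams(population_size=100, max_iteration=50)
        for s in range(n_runs):
            r = np.random.default_rng(s)
            best = evolve(own, doms, history, params, r)
            rand = init_population(own, doms, GAParams(population_size=2), r)[0]
            if fitness(best, own, history) >= fitness(rand, own, history):
                wins += 1
        assert wins >= 95


class TestWeightRefinement:
    def test_concession_weights_hand_example(self):
        ledger = ConcessionLedger(
            widths=np.array([1.0, 1.0]),
            steps=np.array([0.01, 0.01]),
            c=np.array([0.1, 0.4]),
        )
        np.testing.assert_allclose(concession_weights(ledger), [0.8, 0.2], atol=1e-12)

    def test_symmetry(self):
        ledger = ConcessionLedger(
            widths=np.full(4, 2.0), steps=np.full(4, 0.02), c=np.full(4, 0.3)
        )
        np.testing.assert_allclose(concession_weights(ledger), 0.25, atol=1e-12)

    def test_single_issue(self):
        ledger = ConcessionLedger(
            widths=np.array([5.0]), steps=np.array([0.05]), c=np.array([0.7])
        )
        np.testing.assert_allclose(concession_weights(ledger), [1.0])

    def test_zero_concession_floored_at_step(self):
        ledger = ConcessionLedger(
            widths=np.array([1.0, 1.0]),
            steps=np.array([0.1, 0.1]),
            c=np.array([0.0, 0.1]),
        )
        # floored: raw (1/0.1, 1/0.1) -> equal weights
        np.testing.assert_allclose(concession_weights(ledger), [0.5, 0.5])

    def test_ledger_update(self):
        ledger = ConcessionLedger(widths=np.ones(2), steps=np.full(2, 0.1))
        ledger.update((0.2, 0.8), (0.5, 0.6))
        np.testing.assert_allclose(ledger.c, [0.3, 0.2])

    def test_refine_mean(self):
        np.testing.assert_allclose(
            refine_weights(np.array([0.6, 0.4]), np.array([0.2, 0.8])), [0.4, 0.6]
        )

    def test_refine_identity(self):
        w = np.array([0.3, 0.7])
        np.testing.assert_allclose(refine_weights(w, w), w)

    def test_refine_sums_to_one(self, rng):
        for _ in range(20):
            w1 = rng.dirichlet(np.ones(5))
            w2 = rng.dirichlet(np.ones(5))
            assert refine_weights(w1, w2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_refine_length_mismatch(self):
        with pytest.raises(ValueError):
            refine_weights(np.array([1.0]), np.array([0.5, 0.5]))
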