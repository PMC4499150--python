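"""Tests for the BDeu scorer, GA, MCMC and consensus machinery."""

import itertools

import numpy as np
import pytest

from loopnet import learning, synthetic
from loopnet.datatypes import GeneNetwork, PriorEdge, PriorTable
from loopnet.learning import BDeuScorer, GAConfig, MCMCConfig, ScoreConfig


def _prior_from_truth(truth, p=0.8):
    return PriorTable(
        PriorEdge(u, v, p, ("chip", "same_cell", "PRE_direct")) for u, v in truth.edges
    )


@pytest.fixture(scope="module")
def small_instance():
    truth = synthetic.generate_true_network(6, 2, 2.0, seed=17)
    data = synthetic.simulate_expression(truth, 200, 0.5, seed=18).discretize()
    prior = _prior_from_truth(truth)
    return truth, data, prior


class TestScoreNetwork:
    def test_empty_network_is_sum_of_parent_free_families(self, small_instance):
        _, data, prior = small_instance
        scorer = BDeuScorer(data, prior, ScoreConfig())
        empty = GeneNetwork(data.genes)
        expected = sum(scorer.family_score(i, ()) for i in range(len(data.genes)))
        assert learning.score_network(empty, data, prior, scorer=scorer) == pytest.approx(
            expected
        )

    def test_true_strong_edge_improves_score(self, small_instance):
        truth, data, prior = small_instance
        u, v = truth.edges[0]
        empty = GeneNetwork(data.genes)
        with_edge = GeneNetwork(data.genes, [(u, v)])
        s0 = learning.score_network(empty, data, prior)
        s1 = learning.score_network(with_edge, data, prior)
        assert s1 > s0

    def test_incremental_equals_scratch_after_random_toggles(self, small_instance):
        """Decomposability: maintaining the score through 1000 single-edge
        toggles agrees with full rescoring to 1e-6."""
        _, data, prior = small_instance
        scorer = BDeuScorer(data, prior, ScoreConfig())
        rng = np.random.default_rng(0)
        n = len(data.genes)
        dag = learning._DAG(n)
        score = scorer.dag_score(dag)
        for _ in range(1000):
            u = int(rng.integers(n))
            v = int(rng.integers(n - 1))
            if v >= u:
                v += 1
            if dag.has_edge(u, v):
                old = scorer.family_score(v, tuple(sorted(dag.parents[v])))
                dag.remove_edge(u, v)
                new = scorer.family_score(v, tuple(sorted(dag.parents[v])))
                score += new - old - scorer.edge_prior(u, v)
            elif (
                len(dag.parents[v]) < ScoreConfig().max_parents
                and not dag.creates_cycle(u, v)
            ):
                old = scorer.family_score(v, tuple(sorted(dag.parents[v])))
                dag.add_edge(u, v)
                new = scorer.family_score(v, tuple(sorted(dag.parents[v])))
                score += new - old + scorer.edge_prior(u, v)
        assert score == pytest.approx(scorer.dag_score(dag), abs=1e-6)

    def test_cyclic_network_rejected(self, small_instance):
        _, data, prior = small_instance
        g = data.genes
        cyc = GeneNetwork(g, [(g[0], g[1]), (g[1], g[0])])
        with pytest.raises(ValueError, match="cyclic"):
            learning.score_network(cyc, data, prior)

    def test_missing_node_rejected(self, small_instance):
        _, data, prior = small_instance
        net = GeneNetwork(("ZZZ", data.genes[0]), [("ZZZ", data.genes[0])])
        with pytest.raises(ValueError, match="missing"):
            learning.score_network(net, data, prior)


class TestInitPopulation:
    def test_empty_prior_zero_rate_gives_empty_chromosomes(self, small_instance):
        _, data, _ = small_instance
        cfg = GAConfig.scaled(population_size=8)
        cfg = GAConfig(population_size=8, poisson_init_rate=0.0)
        pop = learning.init_population(PriorTable(), cfg, seed=0, data=data)
        assert all(len(net.edges) == 0 for net in pop)

    def test_certain_prior_pair_always_included(self, small_instance):
        _, data, _ = small_instance
        g = data.genes
        prior = PriorTable([PriorEdge(g[0], g[1], 1.0, ("chip", "same_cell", "PRE_direct"))])
        cfg = GAConfig(population_size=16, poisson_init_rate=0.0)
        pop = learning.init_population(prior, cfg, seed=1, data=data)
        assert all((g[0], g[1]) in net.edges for net in pop)

    def test_poisson_extra_links_mean(self, small_instance):
        truth, data, prior = small_instance
        rate = 1.5
        cfg = GAConfig(population_size=128, poisson_init_rate=rate)
        prior_zero = PriorTable(
            PriorEdge(e.regulator, e.target, 0.05, e.cls) for e in prior
        )
        pop = learning.init_population(prior_zero, cfg, seed=2, data=data)
        n_reg = len({e.regulator for e in prior})
        # prior pairs enter at rate 0.05 each; the rest are Poisson extras
        mean_edges = np.mean([len(net.edges) for net in pop])
        expected = n_reg * rate + 0.05 * len(prior)
        assert abs(mean_edges - expected) / expected < 0.35


class TestEvolve:
    def test_elitism_keeps_best_fitness_non_decreasing(self, small_instance):
        _, data, prior = small_instance
        cfg = GAConfig(population_size=12, max_generations=40)
        pop = learning.init_population(prior, cfg, 3, data=data)
        _, trace = learning.evolve(pop, data, prior, cfg, seed=4)
        fit = trace.best_fitness
        assert all(b >= a for a, b in zip(fit, fit[1:]))

    def test_degenerate_ga_constant_after_first_generation(self, small_instance):
        # no mutation, no crossover, deterministic refresh (certain priors,
        # zero Poisson rate): elitism pins the best fitness after gen 1
        _, data, _ = small_instance
        g = data.genes
        prior = PriorTable([PriorEdge(g[0], g[1], 1.0, ("chip", "same_cell", "PRE_direct"))])
        cfg = GAConfig(
            population_size=8,
            max_generations=30,
            mutation_rate_per_group=(0.0, 0.0, 0.0, 0.0),
            poisson_init_rate=0.0,
            plateau_window=1000,
        )
        pop = learning.init_population(prior, cfg, 5, data=data)
        _, trace = learning.evolve(pop, data, prior, cfg, seed=6, crossover=False)
        assert len(set(trace.best_fitness)) == 1

    def test_plateau_stopping_terminates_early(self, small_instance):
        _, data, prior = small_instance
        cfg = GAConfig(population_size=12, max_generations=5000, plateau_window=30)
        pop = learning.init_population(prior, cfg, 7, data=data)
        _, trace = learning.evolve(pop, data, prior, cfg, seed=8)
        assert trace.generation[-1] < 5000


class TestConsensus:
    def _nets(self):
        nodes = ("a", "b", "c")
        n1 = GeneNetwork(nodes, [("a", "b"), ("b", "c")])
        n2 = GeneNetwork(nodes, [("a", "b"), ("a", "c")])
        n3 = GeneNetwork(nodes, [("a", "b")])
        return [n1, n2, n3]

    def test_min_support_one_is_union(self):
        out = learning.consensus_network(self._nets(), 1)
        assert out.edges == {("a", "b"), ("b", "c"), ("a", "c")}

    def test_min_support_n_is_intersection(self):
        out = learning.consensus_network(self._nets(), 3)
        assert out.edges == {("a", "b")}

    def test_single_shared_edge_at_support_two(self):
        nodes = ("a", "b", "c")
        nets = [
            GeneNetwork(nodes, [("a", "b"), ("b", "c")]),
            GeneNetwork(nodes, [("a", "b"), ("a", "c")]),
            GeneNetwork(nodes, [("a", "b"), ("c", "b")]),
        ]
        out = learning.consensus_network(nets, 2)
        assert out.edges == {("a", "b")}
        assert out.support[("a", "b")] == 3

    def test_cyclic_consensus_flagged(self):
        nodes = ("a", "b")
        nets = [GeneNetwork(nodes, [("a", "b")]), GeneNetwork(nodes, [("b", "a")])]
        out = learning.consensus_network(nets, 1)
        assert out.metadata["is_acyclic"] is False

    def test_errors(self):
        with pytest.raises(ValueError):
            learning.consensus_network([], 1)
        with pytest.raises(ValueError):
            learning.consensus_network(self._nets(), 5)


def _all_dags(nodes):
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    out = []
    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        g = GeneNetwork(nodes, edges)
        if g.is_acyclic():
            out.append(g)
    return out


class TestMcmcRefine:
    def test_cold_chain_stays_at_global_optimum(self):
        truth = synthetic.generate_true_network(3, 1, 1.5, seed=5)
        data = synthetic.simulate_expression(truth, 120, 0.5, seed=6).discretize()
        prior = _prior_from_truth(truth)
        scorer = BDeuScorer(data, prior, ScoreConfig())
        dags = _all_dags(list(truth.nodes))
        scores = [learning.score_network(g, data, prior, scorer=scorer) for g in dags]
        best = dags[int(np.argmax(scores))]
        _, out = learning.mcmc_refine(
            best, data, prior, n_steps=5000, temperature=1e-9, seed=7, scorer=scorer
        )
        assert out.edges == best.edges

    def test_acyclic_states_and_frequencies_in_unit_interval(self, small_instance):
        _, data, prior = small_instance
        freqs, best = learning.mcmc_refine(
            GeneNetwork(data.genes), data, prior, n_steps=4000, seed=8
        )
        assert best.is_acyclic()
        assert all(0 <= f <= 1 for f in freqs.values())

    def test_rejects_zero_steps(self, small_instance):
        _, data, prior = small_instance
        with pytest.raises(ValueError):
            learning.mcmc_refine(GeneNetwork(data.genes), data, prior, n_steps=0)


class TestBuildGlobalNetwork:
    def test_single_run_reduces_to_evolve_plus_refine(self, small_instance):
        _, data, prior = small_instance
        ga = GAConfig(population_size=8, max_generations=50, n_runs=1,
                      consensus_min_support=1)
        mc = MCMCConfig(n_steps=2000)
        net = learning.build_global_network(data, prior, ga, mc, seed=9)
        ss = np.random.SeedSequence(9)
        run_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 3))
        scorer = BDeuScorer(data, prior, ScoreConfig())
        pop = learning.init_population(prior, ga, run_seed, scorer=scorer)
        ga_best, _ = learning.evolve(pop, data, prior, ga, run_seed + 1, scorer=scorer)
        _, refined = learning.mcmc_refine(
            ga_best, data, prior, n_steps=2000, seed=run_seed + 2, scorer=scorer
        )
        assert net.edges == refined.edges

    def test_deterministic_and_thread_invariant(self, small_instance):
        _, data, prior = small_instance
        ga = GAConfig(population_size=8, max_generations=40, n_runs=4,
                      consensus_min_support=2)
        mc = MCMCConfig(n_steps=1000)
        a = learning.build_global_network(data, prior, ga, mc, seed=10, threads=1)
        b = learning.build_global_network(data, prior, ga, mc, seed=10, threads=1)
        c = learning.build_global_network(data, prior, ga, mc, seed=10, threads=2)
        assert a.edges == b.edges == c.edges
        assert a.support == b.support == c.support
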