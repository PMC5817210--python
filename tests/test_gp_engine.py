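"""GP engine: tree semantics, operators, constant fitting, evolution."""

import math

import numpy as np
import pytest

from conftest import oracle_evaluate
from qtgp import gp_engine as gp
from qtgp.gp_engine import GPConfig, Individual
from qtgp.qt_model import CANONICAL_PARSE, equation_tree, eval_dqtc, equation_variables


@pytest.fixture()
def config():
    return GPConfig(population_size=20, evaluation_budget=2000, size_limit=16,
                    variables=("x1", "x2"))


class TestEvaluate:
    def test_variable_identity(self):
        data = {"x1": np.array([1.0, 2.0, 3.0])}
        out = gp.evaluate(("var", "x1"), [], data)
        assert np.array_equal(out, data["x1"])

    def test_protected_exp_clamps(self):
        out = gp.evaluate(("exp", ("var", "x")), [], {"x": np.array([1000.0])})
        assert np.isfinite(out[0]) and out[0] == pytest.approx(math.exp(50))

    def test_unknown_variable_raises(self):
        with pytest.raises(KeyError):
            gp.evaluate(("var", "nope"), [], {"x": np.ones(3)})

    def test_equation_tree_matches_white_box_model(self):
        rng = np.random.default_rng(0)
        rec = {n: rng.uniform(0.1, 0.9, 500) for n in equation_variables()}
        tree, constants = equation_tree()
        a = gp.evaluate(tree, constants, rec)
        b = np.asarray(eval_dqtc(rec))
        assert np.max(np.abs(a - b)) < 1e-10

    def test_matches_independent_oracle_on_random_trees(self, config):
        """Vectorized evaluation agrees with the scalar sympy path."""
        rng = np.random.default_rng(42)
        data = {v: rng.uniform(-3, 3, 50) for v in config.variables}
        for _ in range(100):
            tree = gp.random_tree(config, rng)
            constants = rng.uniform(-5, 5, gp.count_constants(tree))
            a = np.asarray(gp.evaluate(tree, constants, data), float)
            b = oracle_evaluate(tree, constants, data)
            np.testing.assert_allclose(a, np.broadcast_to(b, a.shape) if a.shape else b,
                                       rtol=1e-10, atol=1e-10)


class TestPrefixGrammar:
    def test_round_trip_random_trees(self, config):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tree = gp.random_tree(config, rng)
            assert gp.from_prefix(gp.to_prefix(tree)) == tree

    def test_trailing_tokens_rejected(self):
        with pytest.raises(ValueError):
            gp.from_prefix("add x1 x2 x3")


class TestVariation:
    def test_random_tree_respects_size_limit(self, config):
        rng = np.random.default_rng(2)
        for _ in range(200):
            assert gp.tree_size(gp.random_tree(config, rng)) <= config.size_limit

    def test_crossover_respects_size_limit(self, config):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = gp.random_tree(config, rng)
            b = gp.random_tree(config, rng)
            child = gp.crossover(a, b, config, rng)
            assert gp.tree_size(child) <= config.size_limit

    def test_fixed_seed_gives_identical_offspring(self, config):
        a = gp.random_tree(config, np.random.default_rng(4))
        b = gp.random_tree(config, np.random.default_rng(5))
        c1 = gp.crossover(a, b, config, np.random.default_rng(6))
        c2 = gp.crossover(a, b, config, np.random.default_rng(6))
        assert c1 == c2

    def test_jitter_mutation_keeps_structure(self, config):
        tree = ("mul", ("const", 0), ("var", "x1"))
        constants = np.array([2.0])
        new_tree, new_constants = gp.mutate(tree, constants, config,
                                            np.random.default_rng(7), kind="jitter")
        assert new_tree == tree
        assert new_constants[0] != 2.0

    def test_mutation_respects_size_limit(self, config):
        rng = np.random.default_rng(8)
        for _ in range(200):
            tree = gp.random_tree(config, rng)
            constants = rng.uniform(-1, 1, gp.count_constants(tree))
            new_tree, _ = gp.mutate(tree, constants, config, rng)
            assert gp.tree_size(new_tree) <= config.size_limit


class TestOptimizeConstants:
    def test_linear_coefficient_recovery(self):
        rng = np.random.default_rng(9)
        data = {"x1": rng.uniform(-1, 1, 200)}
        tree = ("mul", ("const", 0), ("var", "x1"))
        constants, rmse = gp.optimize_constants(tree, data, 3.0 * data["x1"], seed=1)
        assert constants[0] == pytest.approx(3.0, abs=1e-6)
        assert rmse < 1e-8

    def test_two_constant_recovery_on_noiseless_data(self):
        rng = np.random.default_rng(10)
        data = {"x1": rng.uniform(-2, 2, 300), "x2": rng.uniform(-2, 2, 300)}
        tree = ("add", ("mul", ("const", 0), ("var", "x1")),
                ("mul", ("const", 1), ("sin", ("var", "x2"))))
        y = 1.7 * data["x1"] + 0.4 * np.sin(data["x2"])
        constants, _ = gp.optimize_constants(tree, data, y, seed=2,
                                             init=np.array([1.5, 0.5]))
        assert np.allclose(constants, [1.7, 0.4], atol=1e-4)

    def test_no_constants_rejected(self):
        with pytest.raises(ValueError, match="no constant"):
            gp.optimize_constants(("var", "x1"), {"x1": np.ones(5)}, np.ones(5), seed=1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        data = {"x1": rng.uniform(-1, 1, 100)}
        tree = ("mul", ("const", 0), ("var", "x1"))
        y = 2.0 * data["x1"]
        a = gp.optimize_constants(tree, data, y, seed=3)
        b = gp.optimize_constants(tree, data, y, seed=3)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]


class TestEvolve:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(12)
        data = {"x1": rng.uniform(-3, 3, 300), "x2": rng.uniform(-3, 3, 300)}
        return data, np.sin(data["x1"]) + 2.0 * data["x2"]

    def test_budget_below_one_generation_rejected(self, planted, config):
        data, y = planted
        cfg = GPConfig(population_size=100, evaluation_budget=150, size_limit=16,
                       variables=("x1", "x2"))
        with pytest.raises(ValueError, match="budget"):
            gp.evolve(data, y, cfg, seed=1)

    def test_seed_required(self, planted, config):
        data, y = planted
        with pytest.raises(ValueError, match="seed"):
            gp.evolve(data, y, config)

    def test_archive_mutually_nondominated(self, planted, config):
        data, y = planted
        archive = gp.evolve(data, y, config, seed=2)
        keys = [(i.fitness, i.complexity, i.age) for i in archive]
        for i, ki in enumerate(keys):
            for j, kj in enumerate(keys):
                if i != j:
                    assert not gp._dominates(kj, ki)

    def test_population_size_constant_and_fitness_monotone(self, planted):
        data, y = planted
        sizes, bests = [], []
        cfg = GPConfig(population_size=30, evaluation_budget=3000, size_limit=16,
                       variables=("x1", "x2"))
        gp.evolve(data, y, cfg, seed=3,
                  callback=lambda g, e, pop, arch: (
                      sizes.append(len(pop)),
                      bests.append(min(i.fitness for i in arch))))
        assert set(sizes) == {30}
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(bests, bests[1:]))

    def test_reproducible_for_fixed_seed(self, planted, config):
        data, y = planted
        a = gp.evolve(data, y, config, seed=4)
        b = gp.evolve(data, y, config, seed=4)
        assert [gp.to_prefix(i.tree) for i in a] == [gp.to_prefix(i.tree) for i in b]
        assert [i.fitness for i in a] == [i.fitness for i in b]

    def test_archive_tournament_mode_runs(self, planted):
        data, y = planted
        cfg = GPConfig(population_size=30, evaluation_budget=3000, size_limit=16,
                       variables=("x1", "x2"), selection="archive_tournament")
        archive = gp.evolve(data, y, cfg, seed=5)
        assert len(archive) >= 1

    def test_planted_target_recovered(self, planted):
        data, y = planted
        cfg = GPConfig(population_size=100, evaluation_budget=50_000, size_limit=16,
                       variables=("x1", "x2"), elite_cadence_factor=100,
                       terminate_fitness=0.005)
        archive = gp.evolve(data, y, cfg, seed=6)
        assert min(i.fitness for i in archive) < 0.01


class TestSelectFinal:
    def _ind(self, cv, complexity, n_constants):
        # build a chain tree of the requested size with n_constants slots
        tree = ("const", 0) if n_constants else ("var", "x1")
        for i in range(1, n_constants):
            tree = ("add", tree, ("const", i))
        while gp.tree_size(tree) < complexity:
            tree = ("neg", tree)
        ind = Individual(tree=tree, constants=np.zeros(n_constants),
                         fitness=cv, cv_error=cv)
        assert ind.complexity == complexity and ind.n_constants == n_constants
        return ind

    def test_three_candidate_worked_example(self):
        a = self._ind(0.10, 20, 3)
        b = self._ind(0.104, 12, 2)
        c = self._ind(0.20, 5, 1)
        assert gp.select_final([a, b, c]) is b

    def test_equal_cv_prefers_low_complexity(self):
        a = self._ind(0.10, 30, 1)
        b = self._ind(0.10, 12, 1)
        assert gp.select_final([a, b]) is b

    def test_dominated_candidate_never_selected(self):
        good = self._ind(0.10, 12, 1)
        dominated = self._ind(0.20, 14, 2)
        assert gp.select_final([good, dominated]) is good

    def test_empty_or_unscored_archive_rejected(self):
        with pytest.raises(ValueError):
            gp.select_final([])
        unscored = Individual(tree=("var", "x1"), constants=np.zeros(0), fitness=1.0)
        with pytest.raises(ValueError):
            gp.select_final([unscored])
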