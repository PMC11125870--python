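"""GP engine: protected evaluation, variation operators, evolution loop."""

import math

import numpy as np
import pytest

import markergp as mg
from markergp import (
    GAConfig,
    Node,
    crossover,
    evaluate,
    evolve,
    mutate,
    parse_infix,
    random_tree,
    tournament_select,
)
from conftest import random_trees


def leaf_t():
    return Node("t")


def const(v):
    return Node("const", value=v)


# -- independent oracle ----------------------------------------------------
# A naive scalar evaluator written separately from the package's vectorized
# one, implementing the same documented protection conventions.  It calls
# numpy's scalar kernels so that agreement can be asserted bit-exactly.

def oracle_eval(node, t, eps=1e-6):
    if node.symbol == "t":
        return float(t)
    if node.symbol == "const":
        return node.value
    args = [oracle_eval(c, t, eps) for c in node.children]
    s = node.symbol
    if s == "add":
        return args[0] + args[1]
    if s == "sub":
        return args[0] - args[1]
    if s == "mult":
        return args[0] * args[1]
    if s == "div":
        return args[0] / args[1] if abs(args[1]) > eps else 1.0
    if s == "sqrt":
        return float(np.sqrt(abs(args[0])))
    if s == "log":
        return float(np.log(abs(args[0]))) if abs(args[0]) > eps else 0.0
    if s == "abs":
        return abs(args[0])
    if s == "neg":
        return -args[0]
    if s == "inv":
        return 1.0 / args[0] if abs(args[0]) > eps else 1.0
    if s == "max":
        return max(args)
    if s == "min":
        return min(args)
    if s == "sin":
        return float(np.sin(args[0]))
    if s == "cos":
        return float(np.cos(args[0]))
    if s == "tan":
        return min(max(float(np.tan(args[0])), -1e6), 1e6)
    raise AssertionError(s)


class TestEvaluate:
    def test_simple_addition(self):
        assert evaluate(Node("add", (leaf_t(), const(2.0))), 3.0) == 5.0

    def test_protected_division_convention(self):
        assert evaluate(Node("div", (const(1.0), const(0.0))), 0.0) == 1.0

    def test_nested_expression(self):
        tree = Node("mult", (Node("sin", (leaf_t(),)),
                             Node("max", (leaf_t(), const(2.0)))))
        assert evaluate(tree, 1.0) == pytest.approx(math.sin(1.0) * 2, abs=1e-12)

    @pytest.mark.parametrize(
        "expr,t,expected",
        [
            ("log(0.0)", 0.0, 0.0),
            ("sqrt(-4.0)", 0.0, 2.0),
            ("inv(0.0)", 0.0, 1.0),
            ("neg(abs(-3.0))", 0.0, -3.0),
            ("min(t, 1.0)", 4.0, 1.0),
        ],
    )
    def test_protection_conventions(self, expr, t, expected):
        assert evaluate(parse_infix(expr), t) == expected

    def test_matches_naive_oracle_on_random_trees(self, rng):
        config = GAConfig(seed=0)
        grid = [1.0, 1.375, 1.7916666666666667, 2.1666666666666665, 4.0]
        for tree in random_trees(config, rng, 1000):
            mine = evaluate(tree, np.array(grid))
            theirs = np.array([oracle_eval(tree, t) for t in grid])
            assert np.array_equal(mine, theirs), mg.to_infix(tree)

    def test_totality_on_random_trees(self, rng):
        config = GAConfig(seed=0)
        grid = np.linspace(0.0, 4.0, 9)
        for tree in random_trees(config, rng, 2000):
            assert np.all(np.isfinite(evaluate(tree, grid)))


class TestRandomTree:
    def test_zero_depth_gives_leaf(self, rng):
        config = GAConfig(seed=0)
        for _ in range(50):
            tree = random_tree(config, 0, rng)
            assert tree.is_leaf

    def test_invariant_sweep(self, rng):
        config = GAConfig(seed=0)
        for tree in random_trees(config, rng, 5000):
            assert tree.depth() <= 4
            for node in tree.preorder():
                if node.symbol in mg.FUNCTIONS:
                    assert len(node.children) == mg.FUNCTIONS[node.symbol][0]
                else:
                    assert node.is_leaf
                if node.symbol == "const":
                    lo, hi = config.constant_range
                    assert lo <= node.value <= hi

    def test_function_set_restriction_is_respected(self, rng):
        config = GAConfig(function_set=("add", "mult"), seed=0)
        for tree in random_trees(config, rng, 300):
            for node in tree.preorder():
                assert node.symbol in {"add", "mult", "t", "const"}


class TestVariation:
    def test_crossover_of_leaves_returns_one_of_them(self):
        config = GAConfig(seed=0)
        rng = np.random.default_rng(4)
        a, b = const(1.5), leaf_t()
        for _ in range(20):
            child = crossover(a, b, config, rng)
            assert child in (a, b) or child == a or child == b

    def test_crossover_respects_depth_limit(self, rng):
        config = GAConfig(max_depth=6, seed=0)
        parents = random_trees(config, rng, 200, depth=6)
        for a, b in zip(parents[::2], parents[1::2]):
            child = crossover(a, b, config, rng)
            assert child.depth() <= config.max_depth

    def test_crossover_deterministic_under_seed(self, rng):
        config = GAConfig(seed=0)
        a, b = random_trees(config, rng, 2, depth=4)
        c1 = crossover(a, b, config, np.random.default_rng(9))
        c2 = crossover(a, b, config, np.random.default_rng(9))
        assert c1 == c2

    def test_crossover_leaves_parents_untouched(self, rng):
        config = GAConfig(seed=0)
        a, b = random_trees(config, rng, 2, depth=4)
        before = (mg.to_infix(a), mg.to_infix(b))
        crossover(a, b, config, np.random.default_rng(1))
        assert (mg.to_infix(a), mg.to_infix(b)) == before

    def test_mutation_preserves_invariants(self, rng):
        config = GAConfig(seed=0)
        for tree in random_trees(config, rng, 500):
            mutant = mutate(tree, config, rng)
            assert mutant.depth() <= config.max_depth
            for node in mutant.preorder():
                if node.symbol in mg.FUNCTIONS:
                    assert len(node.children) == mg.FUNCTIONS[node.symbol][0]

    def test_point_mutation_preserves_arity(self):
        config = GAConfig(
            p_crossover=0.0,
            p_subtree_mutation=0.0,
            p_point_mutation=1.0,
            p_reproduction=0.0,
            seed=0,
        )
        tree = parse_infix("sin(add(t, 2.0))")
        for s in range(40):
            mutant = mutate(tree, config, np.random.default_rng(s))
            assert [len(n.children) for n in mutant.preorder()] == [
                len(n.children) for n in tree.preorder()
            ]

    def test_mutation_deterministic_under_seed(self, rng):
        config = GAConfig(seed=0)
        (tree,) = random_trees(config, rng, 1, depth=4)
        m1 = mutate(tree, config, np.random.default_rng(33))
        m2 = mutate(tree, config, np.random.default_rng(33))
        assert m1 == m2


class TestTournament:
    def _population(self, fitnesses):
        return [
            mg.Individual(const(0.0), f, f, 1) for f in fitnesses
        ]

    def test_full_tournament_always_selects_best(self):
        pop = self._population([0.1, 0.9, 0.5])
        config = GAConfig(population_size=3, tournament_size=3, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert tournament_select(pop, config, rng).raw_fitness == 0.9

    def test_oversized_tournament_rejected(self):
        pop = self._population([0.1])
        config = GAConfig(population_size=2, tournament_size=2, seed=0)
        with pytest.raises(ValueError, match="tournament_size"):
            tournament_select(pop, config, rng=np.random.default_rng(0))

    def test_selection_probability_matches_closed_form(self):
        # best of 10 under tournaments of 2: P = 1 - C(9,2)/C(10,2) = 0.2
        pop = self._population(np.linspace(0.0, 0.9, 10))
        config = GAConfig(population_size=10, tournament_size=2, seed=0)
        rng = np.random.default_rng(123)
        hits = sum(
            tournament_select(pop, config, rng).raw_fitness == 0.9
            for _ in range(100_000)
        )
        assert hits / 100_000 == pytest.approx(0.2, abs=0.01)

    def test_fitness_tie_broken_by_node_count(self):
        small = mg.Individual(const(0.0), 0.5, 0.5, 1)
        big = mg.Individual(parse_infix("add(t, 1.0)"), 0.5, 0.5, 3)
        config = GAConfig(population_size=2, tournament_size=2, seed=0)
        pick = tournament_select([big, small], config, np.random.default_rng(0))
        assert pick is small


class TestEvolve:
    def test_recovers_noiseless_linear_target(self):
        times = np.array([1.0, 1.375, 43 / 24, 52 / 24])
        values = 2 * times + 1
        result = evolve(times, values, GAConfig(seed=17))
        assert result.best.raw_fitness >= 0.999

    def test_constant_data_convention(self, small_config):
        times = np.array([1.0, 2.0, 3.0])
        result = evolve(times, np.full(3, 7.5), small_config)
        assert result.best.raw_fitness == 1.0

    def test_deterministic_best_expression(self, small_config):
        times = np.array([1.0, 1.375, 43 / 24, 52 / 24])
        values = np.array([3.0, 2.0, 2.5, 4.0])
        r1 = evolve(times, values, small_config)
        r2 = evolve(times, values, small_config)
        assert mg.to_infix(r1.best.tree) == mg.to_infix(r2.best.tree)
        assert r1.history == r2.history

    def test_best_so_far_history_is_monotone(self, small_config):
        times = np.array([1.0, 1.375, 43 / 24, 52 / 24])
        values = np.array([5.0, 1.0, 4.0, 2.0])
        result = evolve(times, values, small_config)
        assert np.all(np.diff(result.history) >= 0)

    def test_rejects_fewer_than_two_distinct_timepoints(self, small_config):
        with pytest.raises(ValueError, match="distinct timepoints"):
            evolve(np.array([1.0, 1.0]), np.array([2.0, 2.0]), small_config)

    def test_closed_form_limit_identity_found_at_initialization(self):
        # restricted to {add, mult} with constants pinned to 1, y = t is in
        # the initial population for some seed: generation-0 R^2 reaches 1
        times = np.linspace(1.0, 3.0, 5)
        hit = False
        for seed in range(20):
            config = GAConfig(
                function_set=("add", "mult"),
                constant_range=(1.0 - 1e-12, 1.0 + 1e-12),
                max_generations=0,
                polish_constants=False,
                seed=seed,
            )
            result = evolve(times, times.copy(), config)
            if result.history[0] == 1.0:
                hit = True
                break
        assert hit


class TestHallOfFameAndPolish:
    def test_polish_recovers_exact_constants(self):
        # shape fixed to a + b*t with perturbed constants: polishing should
        # drive the training fit to machine-level R^2
        times = np.array([1.0, 1.375, 43 / 24, 52 / 24])
        values = 2 * times + 1
        config = GAConfig(seed=0)
        rough = parse_infix("add(mult(1.8, t), 1.4)")
        polished = mg.markergp._polish_constants(rough, times, values, config)
        assert mg.r_squared(values, evaluate(polished, times)) >= 1 - 1e-9

    def test_hall_contains_distinct_shapes(self, small_config):
        times = np.array([1.0, 1.375, 43 / 24, 52 / 24])
        values = np.array([1.0, 1.9, 3.1, 3.9])
        result = evolve(times, values, small_config)
        sigs = {
            tuple(n.symbol for n in ind.tree.preorder()) for ind in result.hall
        }
        assert len(sigs) == len(result.hall) > 1
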