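import numpy as np
import pytest

import evokgsim as ek
from evokgsim import expr
from evokgsim.expr import parse_expression, simplify_tree, trees_equivalent
from evokgsim.gp import DegenerateTrainingError, GPParams, _init_population
from evokgsim.similarity import FeatureTable

# the published example combination: max(BP, CC) * max(BP, MF)
EXAMPLE = "mul(max(X0, X1), max(X0, X2))"


def table_from(X, y):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        pairs=[(f"a{i}", f"b{i}") for i in range(len(X))],
        aspects=("BP", "CC", "MF"),
        scores=X,
        measure="ResnikMax",
        labels=np.asarray(y, dtype=int),
    )


class TestEvaluateModel:
    def test_example_combination(self):
        tree = parse_expression(EXAMPLE)
        assert ek.evaluate_model(tree, (0.2, 0.8, 0.1)) == pytest.approx(0.16)

    def test_identity_tree(self):
        assert ek.evaluate_model(("var", 0), (0.7, 0.0, 0.0)) == pytest.approx(0.7)

    def test_protected_division(self):
        tree = ("div", ("const", 1.0), ("const", 0.0))
        assert ek.evaluate_model(tree, (0, 0, 0)) == 1.0
        near = ("div", ("const", 1.0), ("const", 0.0009))
        assert ek.evaluate_model(near, (0, 0, 0)) == 1.0

    def test_malformed_tree_raises(self):
        with pytest.raises(expr.MalformedTreeError):
            ek.evaluate_model(("mul", ("var", 0)), (0, 0, 0))

    def test_aliases_in_parser(self):
        t = parse_expression("max(BP, CC)")
        assert t == ("max", ("var", 0), ("var", 1))


class TestFitness:
    def test_perfect_model_zero_rmse(self):
        table = table_from([[1, 0, 0], [0, 0, 0]], [1, 0])
        assert ek.fitness(("var", 0), table) == pytest.approx(0.0)

    def test_constant_half_on_balanced_labels(self):
        table = table_from([[0, 0, 0]] * 4, [1, 1, 0, 0])
        assert ek.fitness(("const", 0.5), table) == pytest.approx(0.5)

    def test_example_model_hand_rmse(self):
        X = [[0.2, 0.8, 0.1], [0.9, 0.9, 0.9], [0.1, 0.1, 0.1], [0.5, 1.0, 1.0]]
        y = [0, 1, 0, 1]
        tree = parse_expression(EXAMPLE)
        outs = [ek.evaluate_model(tree, row) for row in X]
        expected = float(np.sqrt(np.mean((np.array(outs) - np.array(y, float)) ** 2)))
        assert ek.fitness(tree, table_from(X, y)) == pytest.approx(expected)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ek.fitness(("var", 0), table_from(np.zeros((0, 3)), []))


class TestPredict:
    @pytest.mark.parametrize(
        "value,expected", [(0.16, 0), (0.5, 0), (0.51, 1)]
    )
    def test_strict_half_cutoff(self, value, expected):
        table = table_from([[0, 0, 0]], [0])
        assert ek.predict(("const", value), table)[0] == expected


class TestEvolve:
    def test_threshold_rule_is_recoverable(self):
        # labels follow 1[X0 > 0.5], which coincides with the 0.5 decision
        # cutoff, so an accurate model is reachable by the identity X0
        rng = np.random.default_rng(5)
        X = rng.random((1000, 3))
        y = (X[:, 0] > 0.5).astype(int)
        table = table_from(X, y)
        wafs = []
        for seed in (0, 1, 2):
            model = ek.evolve(
                table, GPParams(population_size=200, generations=30, seed=seed)
            )
            wafs.append(ek.waf(y, ek.predict(model, table)))
        assert np.median(wafs) >= 0.95

    def test_same_seed_same_model(self, labeled_table):
        params = GPParams(population_size=60, generations=8, seed=3)
        m1 = ek.evolve(labeled_table, params)
        m2 = ek.evolve(labeled_table, params)
        assert m1.tree == m2.tree
        assert m1.fitness == m2.fitness

    def test_single_class_labels(self):
        table = table_from([[0.1, 0.2, 0.3]] * 10, [1] * 10)
        with pytest.raises(DegenerateTrainingError):
            ek.evolve(table, GPParams(population_size=20, generations=2))
        model = ek.evolve(
            table, GPParams(population_size=20, generations=2, on_single_class="constant")
        )
        assert model.tree == ("const", 1.0)

    def test_best_penalized_fitness_non_increasing(self, labeled_table):
        model = ek.evolve(
            labeled_table, GPParams(population_size=80, generations=12, seed=1)
        )
        hist = model.history["best_penalized"]
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))

    def test_pure_selection_does_not_degrade_mean_fitness(self, labeled_table):
        params = GPParams(
            population_size=150, generations=8, seed=2,
            parsimony_coefficient=0.0, crossover_prob=0.0,
            subtree_mutation_prob=0.0, hoist_mutation_prob=0.0,
            point_mutation_prob=0.0,
        )
        model = ek.evolve(labeled_table, params)
        means = model.history["mean_raw"]
        # under reproduction-only selection the population mean improves
        # (or stays put) once the initial random population is filtered
        assert means[-1] <= means[0] + 0.05

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            GPParams(crossover_prob=0.9, subtree_mutation_prob=0.2)


class TestSimplify:
    @pytest.mark.parametrize(
        "before,after",
        [
            ("max(X0, X0)", "X0"),
            ("add(sub(X0, X0), X1)", "X1"),
            ("add(mul(0.0, X2), max(X1, X1))", "X1"),
            ("min(X2, X2)", "X2"),
            ("div(X1, 1.0)", "X1"),
            ("mul(1.0, max(X0, X2))", "max(X0, X2)"),
        ],
    )
    def test_rewrites(self, before, after):
        assert simplify_tree(parse_expression(before)) == parse_expression(after)

    def test_protected_division_constant_folds_to_one(self):
        assert simplify_tree(parse_expression("div(X0, 0.0)")) == ("const", 1.0)

    def test_random_evolved_trees_probe_equivalent(self):
        rng = np.random.default_rng(0)
        pop = _init_population(rng, GPParams(population_size=100, generations=0), 3)
        for tree in pop:
            assert trees_equivalent(tree, simplify_tree(tree), tol=1e-9)

    def test_simplify_model_wraps_gpmodel(self):
        model = ek.GPModel(tree=parse_expression("max(X0, X0)"), fitness=0.1)
        assert ek.simplify_model(model).tree == ("var", 0)


class TestModelStats:
    def test_example_tree_length_and_frequencies(self):
        length, freqs = ek.model_stats(parse_expression(EXAMPLE))
        assert length == 7
        assert freqs == {0: 0.5, 1: 0.25, 2: 0.25}

    def test_single_variable_model(self):
        length, freqs = ek.model_stats(("var", 1))
        assert length == 1
        assert freqs[1] == 1.0

    def test_constant_only_model_flags_zero_frequencies(self):
        length, freqs = ek.model_stats(("const", 0.3))
        assert length == 1
        assert all(v == 0.0 for v in freqs.values())


class TestSerialization:
    def test_prefix_infix_json_round_trip(self):
        tree = parse_expression(EXAMPLE)
        model = ek.GPModel(tree=tree, fitness=0.0)
        assert model.to_prefix() == "mul(max(X0, X1), max(X0, X2))"
        assert model.to_infix(["BP", "CC", "MF"]) == "(max(BP, CC) * max(BP, MF))"
        assert expr.tree_from_json(model.to_json()) == tree

    def test_dot_export_mentions_all_nodes(self):
        dot = expr.tree_to_dot(parse_expression(EXAMPLE))
        assert dot.count("label") == 7  # one per tree node


class TestEstimator:
    def test_sklearn_clone_and_determinism(self, labeled_table):
        from sklearn.base import clone

        clf = ek.EvoKGSimClassifier(population_size=60, generations=6, random_state=4)
        c2 = clone(clf)
        p1 = clf.fit(labeled_table.X, labeled_table.y).predict(labeled_table.X)
        p2 = c2.fit(labeled_table.X, labeled_table.y).predict(labeled_table.X)
        np.testing.assert_array_equal(p1, p2)
        assert clf.model_.tree == c2.model_.tree

    def test_decision_function_matches_cutoff(self, labeled_table):
        clf = ek.EvoKGSimClassifier(population_size=40, generations=4, random_state=0)
        clf.fit(labeled_table.X, labeled_table.y)
        raw = clf.decision_function(labeled_table.X)
        np.testing.assert_array_equal(clf.predict(labeled_table.X), (raw > 0.5).astype(int))
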