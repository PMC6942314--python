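"""Genetic-programming combiner for aspect similarity scores.

A vanilla tree-based GP system used in regression mode for binary
classification: class labels are treated as numeric targets (0 = no
interaction, 1 = interaction), raw RMSE is the fitness, selection uses a
parsimony-penalized fitness (RMSE + c * node count), and the evolved
expression classifies a pair as positive when its output strictly exceeds
the natural 0.5 cutoff.

The search is generational with tournament selection; per offspring, one
variation operator is drawn (crossover, subtree / hoist / point mutation,
or reproduction).  Initialization is ramped half-and-half.  The best-ever
individual by penalized fitness is returned (elitist bookkeeping), so the
recorded best-fitness trajectory is non-increasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import expr
from .expr import Tree, count_nodes, eval_tree, simplify_tree, variable_frequencies
from .similarity import FeatureTable

logger = logging.getLogger("evokgsim")

DEFAULT_FUNCTION_SET = ("add", "sub", "mul", "div", "max", "min")


@dataclass
class GPParams:
    """Evolution parameters.

    The headline settings are population 500, 50 generations, the six-way
    function set, RMSE fitness and parsimony coefficient 1e-5; the rest
    follow the conventional defaults of vanilla tree GP systems (tournament
    size 20, ramped half-and-half depths 2-6, crossover 0.9, the three
    mutations at 0.01 each, ephemeral constants uniform in [-1, 1]).
    """

    population_size: int = 500
    generations: int = 50
    function_set: tuple[str, ...] = DEFAULT_FUNCTION_SET
    parsimony_coefficient: float = 1e-5
    tournament_size: int = 20
    init_depth: tuple[int, int] = (2, 6)
    crossover_prob: float = 0.9
    subtree_mutation_prob: float = 0.01
    hoist_mutation_prob: float = 0.01
    point_mutation_prob: float = 0.01
    point_replace_prob: float = 0.05
    constant_range: tuple[float, float] | None = (-1.0, 1.0)
    max_nodes: int = 512
    on_single_class: str = "error"  # or "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.crossover_prob,
            self.subtree_mutation_prob,
            self.hoist_mutation_prob,
            self.point_mutation_prob,
        )
        if any(p < 0 for p in probs) or sum(probs) > 1.0 + 1e-12:
            raise ValueError("variation probabilities must be >= 0 and sum <= 1")
        if self.population_size < 1 or self.generations < 0:
            raise ValueError("population_size >= 1 and generations >= 0 required")
        unknown = set(self.function_set) - set(expr.OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators in function set: {unknown}")


@dataclass
class GPModel:
    """An evolved expression tree with its provenance."""

    tree: Tree
    fitness: float  # raw (unpenalized) RMSE on the training table
    seed: int = 0
    generation: int = 0

    def to_prefix(self, variables: Sequence[str] | None = None) -> str:
        return expr.render_prefix(self.tree, variables)

    def to_infix(self, variables: Sequence[str] | None = None) -> str:
        return expr.render_infix(self.tree, variables)

    def to_json(self) -> str:
        return expr.tree_to_json(self.tree)


class DegenerateTrainingError(ValueError):
    """Training labels contain a single class."""


# ---------------------------------------------------------------------------
# tree generation and variation


def _random_terminal(rng, n_vars, const_range):
    # ephemeral constant with probability 1/(n_vars+1) when enabled
    if const_range is not None:
        choice = rng.integers(0, n_vars + 1)
        if choice == n_vars:
            lo, hi = const_range
            return ("const", float(rng.uniform(lo, hi)))
        return ("var", int(choice))
    return ("var", int(rng.integers(0, n_vars)))


def _random_tree(rng, method, max_depth, n_vars, const_range, function_set):
    # "full" places functions down to max_depth; "grow" may stop early
    if max_depth <= 0 or (method == "grow" and rng.random() < 0.4):
        return _random_terminal(rng, n_vars, const_range)
    op = function_set[rng.integers(0, len(function_set))]
    return (
        op,
        _random_tree(rng, method, max_depth - 1, n_vars, const_range, function_set),
        _random_tree(rng, method, max_depth - 1, n_vars, const_range, function_set),
    )


def _paths(tree: Tree, prefix=()):
    """Preorder list of (path, node)."""
    out = [(prefix, tree)]
    if tree[0] not in ("var", "const"):
        out += _paths(tree[1], prefix + (1,))
        out += _paths(tree[2], prefix + (2,))
    return out


def _replace_at(tree: Tree, path, subtree: Tree) -> Tree:
    if not path:
        return subtree
    i = path[0]
    children = list(tree[1:])
    children[i - 1] = _replace_at(children[i - 1], path[1:], subtree)
    return (tree[0],) + tuple(children)


def _pick_node(rng, tree: Tree, function_bias: float = 0.9):
    """Choose a node path with the standard 90/10 weighting: every internal
    node carries weight 0.9 and every leaf 0.1."""
    nodes = _paths(tree)
    if len(nodes) == 1:
        return nodes[0]
    w = np.array(
        [function_bias if n[0] not in ("var", "const") else 1.0 - function_bias
         for _, n in nodes]
    )
    return nodes[int(rng.choice(len(nodes), p=w / w.sum()))]


def _point_mutate(rng, tree: Tree, params: GPParams, n_vars: int) -> Tree:
    head = tree[0]
    if head in ("var", "const"):
        if rng.random() < params.point_replace_prob:
            return _random_terminal(rng, n_vars, params.constant_range)
        return tree
    left = _point_mutate(rng, tree[1], params, n_vars)
    right = _point_mutate(rng, tree[2], params, n_vars)
    if rng.random() < params.point_replace_prob:
        head = params.function_set[rng.integers(0, len(params.function_set))]
    return (head, left, right)


# ---------------------------------------------------------------------------
# engine


def _init_population(rng, params: GPParams, n_vars: int) -> list[Tree]:
    """Ramped half-and-half over the init depth range."""
    lo, hi = params.init_depth
    pop = []
    for i in range(params.population_size):
        depth = lo + (i % (hi - lo + 1))
        method = "full" if (i // (hi - lo + 1)) % 2 == 0 else "grow"
        pop.append(
            _random_tree(rng, method, depth, n_vars, params.constant_range, params.function_set)
        )
    return pop


def _rmse(tree: Tree, X: np.ndarray, y: np.ndarray) -> float:
    pred = eval_tree(tree, X)
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def evolve(train: FeatureTable | tuple, params: GPParams | None = None) -> GPModel:
    """Evolve a combiner on a labeled feature table.

    Returns the best-ever individual by penalized fitness, carrying its raw
    RMSE, the seed, and the generation in which it appeared.  The run is
    fully deterministic given ``params.seed``.
    """
    params = params or GPParams()
    if isinstance(train, FeatureTable):
        X, y = train.X, train.y
    else:
        X, y = train
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training table")
    if len(np.unique(y)) < 2:
        if params.on_single_class == "constant":
            logger.warning("single-class training labels; returning constant model")
            return GPModel(tree=("const", float(y[0])), fitness=0.0, seed=params.seed)
        raise DegenerateTrainingError("training labels contain a single class")

    n_vars = X.shape[1]
    rng = np.random.default_rng(params.seed)
    population = _init_population(rng, params, n_vars)
    raw = np.array([_rmse(t, X, y) for t in population])
    sizes = np.array([count_nodes(t) for t in population])
    pen = raw + params.parsimony_coefficient * sizes

    best_i = int(np.argmin(pen))
    best = GPModel(tree=population[best_i], fitness=float(raw[best_i]),
                   seed=params.seed, generation=0)
    best_pen = float(pen[best_i])
    history = {"best_penalized": [best_pen], "mean_raw": [float(np.mean(raw))]}

    p_cx = params.crossover_prob
    p_sub = p_cx + params.subtree_mutation_prob
    p_hoist = p_sub + params.hoist_mutation_prob
    p_point = p_hoist + params.point_mutation_prob

    def tournament() -> int:
        contenders = rng.integers(0, params.population_size, params.tournament_size)
        return int(contenders[np.argmin(pen[contenders])])

    for gen in range(1, params.generations + 1):
        offspring: list[Tree] = []
        for _ in range(params.population_size):
            parent = population[tournament()]
            u = rng.random()
            if u < p_cx:
                donor = population[tournament()]
                path, _ = _pick_node(rng, parent)
                _, graft = _pick_node(rng, donor)
                child = _replace_at(parent, path, graft)
            elif u < p_sub:
                # subtree mutation grafts a full ramped program, like the
                # naive-crossover-with-random-program convention
                path, _ = _pick_node(rng, parent)
                depth = int(rng.integers(params.init_depth[0], params.init_depth[1] + 1))
                method = "full" if rng.random() < 0.5 else "grow"
                graft = _random_tree(
                    rng, method, depth, n_vars,
                    params.constant_range, params.function_set,
                )
                child = _replace_at(parent, path, graft)
            elif u < p_hoist:
                path, sub = _pick_node(rng, parent)
                _, inner = _pick_node(rng, sub)
                child = _replace_at(parent, path, inner)
            elif u < p_point:
                child = _point_mutate(rng, parent, params, n_vars)
            else:
                child = parent  # reproduction
            if count_nodes(child) > params.max_nodes:
                child = parent  # reject bloated offspring
            offspring.append(child)
        population = offspring
        raw = np.array([_rmse(t, X, y) for t in population])
        sizes = np.array([count_nodes(t) for t in population])
        pen = raw + params.parsimony_coefficient * sizes
        gen_best = int(np.argmin(pen))
        if pen[gen_best] < best_pen:
            best_pen = float(pen[gen_best])
            best = GPModel(tree=population[gen_best], fitness=float(raw[gen_best]),
                           seed=params.seed, generation=gen)
        history["best_penalized"].append(best_pen)
        history["mean_raw"].append(float(np.mean(raw)))

    best.history = history  # type: ignore[attr-defined]
    return best


# ---------------------------------------------------------------------------
# model-level operations


def evaluate_model(model: GPModel | Tree, features: Sequence[float]) -> float:
    """Evaluate the model at a single aspect-score triple."""
    tree = model.tree if isinstance(model, GPModel) else model
    expr.validate_tree(tree)
    return expr.eval_point(tree, features)


def fitness(model: GPModel | Tree, table: FeatureTable) -> float:
    """Raw (unpenalized) RMSE of the model's outputs against 0/1 labels."""
    if len(table) == 0:
        raise ValueError("empty feature table")
    tree = model.tree if isinstance(model, GPModel) else model
    return _rmse(tree, table.X, table.y.astype(float))


def predict(model: GPModel | Tree, features: FeatureTable | np.ndarray) -> np.ndarray:
    """0/1 labels from the 0.5 cutoff (strictly greater => class 1)."""
    tree = model.tree if isinstance(model, GPModel) else model
    X = features.X if isinstance(features, FeatureTable) else np.asarray(features, float)
    return (eval_tree(tree, X) > 0.5).astype(int)


def simplify_model(model: GPModel) -> GPModel:
    """Remove redundant code; pointwise-equivalent to the original tree."""
    return dc_replace(model, tree=simplify_tree(model.tree))


def model_stats(model: GPModel | Tree, n_vars: int = 3) -> tuple[int, dict[int, float]]:
    """(node count, per-variable share of variable-leaf occurrences).

    Meant to be applied to simplified models.  For constant-only trees all
    frequencies are 0 and a warning is logged.
    """
    tree = model.tree if isinstance(model, GPModel) else model
    freqs = variable_frequencies(tree, n_vars)
    if all(v == 0.0 for v in freqs.values()):
        logger.warning("model_stats: constant-only model, no variable leaves")
    return count_nodes(tree), freqs


# ---------------------------------------------------------------------------
# sklearn estimator


class EvoKGSimClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn interface to the GP combiner.

    ``fit`` evolves an expression over the aspect-score columns of ``X``;
    ``decision_function`` returns the raw expression output and ``predict``
    applies the strict 0.5 cutoff.  Fully deterministic given
    ``random_state``.

    Examples
    --------
    >>> clf = EvoKGSimClassifier(population_size=50, generations=5, random_state=0)
    >>> _ = clf.fit([[0.9, 0.1, 0.2], [0.1, 0.8, 0.3]], [1, 0])
    >>> clf.predict([[0.95, 0.1, 0.1]])
    array([1])
    """

    def __init__(
        self,
        population_size: int = 500,
        generations: int = 50,
        function_set: tuple[str, ...] = DEFAULT_FUNCTION_SET,
        parsimony_coefficient: float = 1e-5,
        tournament_size: int = 20,
        init_depth: tuple[int, int] = (2, 6),
        crossover_prob: float = 0.9,
        subtree_mutation_prob: float = 0.01,
        hoist_mutation_prob: float = 0.01,
        point_mutation_prob: float = 0.01,
        constant_range: tuple[float, float] | None = (-1.0, 1.0),
        max_nodes: int = 512,
        on_single_class: str = "error",
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.generations = generations
        self.function_set = function_set
        self.parsimony_coefficient = parsimony_coefficient
        self.tournament_size = tournament_size
        self.init_depth = init_depth
        self.crossover_prob = crossover_prob
        self.subtree_mutation_prob = subtree_mutation_prob
        self.hoist_mutation_prob = hoist_mutation_prob
        self.point_mutation_prob = point_mutation_prob
        self.constant_range = constant_range
        self.max_nodes = max_nodes
        self.on_single_class = on_single_class
        self.random_state = random_state

    def _params(self) -> GPParams:
        return GPParams(
            population_size=self.population_size,
            generations=self.generations,
            function_set=tuple(self.function_set),
            parsimony_coefficient=self.parsimony_coefficient,
            tournament_size=self.tournament_size,
            init_depth=tuple(self.init_depth),
            crossover_prob=self.crossover_prob,
            subtree_mutation_prob=self.subtree_mutation_prob,
            hoist_mutation_prob=self.hoist_mutation_prob,
            point_mutation_prob=self.point_mutation_prob,
            constant_range=self.constant_range,
            max_nodes=self.max_nodes,
            on_single_class=self.on_single_class,
            seed=int(self.random_state or 0),
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        model = evolve((X, y.astype(float)), self._params())
        self.model_ = model
        self.fitness_ = model.fitness
        self.history_ = getattr(model, "history", None)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return eval_tree(self.model_.tree, np.asarray(X, dtype=float))

    def predict(self, X):
        return (self.decision_function(X) > 0.5).astype(int)

    def expression_(self, variables: Sequence[str] | None = None) -> str:
        check_is_fitted(self, "model_")
        return simplify_model(self.model_).to_prefix(variables)
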