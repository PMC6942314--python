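"""Expression trees over aspect-similarity variables.

Trees are immutable nested tuples::

    ("var", i)            # terminal: aspect variable Xi
    ("const", 0.25)       # terminal: real constant
    ("mul", left, right)  # binary operator node

Operators are ``add``, ``sub``, ``mul``, ``div`` (protected: returns 1 when
the denominator's magnitude is at most 1e-3), ``max`` and ``min`` — all
binary.  The same language expresses evolved classifiers and the ground
truth rules of the synthetic-data generator.
"""

from __future__ import annotations

import json
import re
from typing import Callable, Sequence

import numpy as np

#: protected-division guard: |denominator| <= DIV_EPS yields 1
DIV_EPS = 1e-3

OPERATORS = ("add", "sub", "mul", "div", "max", "min")

Tree = tuple


def _pdiv(a, b):
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    out = np.ones_like(np.broadcast_arrays(a, b)[0], dtype=float)
    ok = np.abs(b) > DIV_EPS
    np.divide(a, b, out=out, where=ok)
    return out


_OP_FN: dict[str, Callable] = {
    "add": np.add,
    "sub": np.subtract,
    "mul": np.multiply,
    "div": _pdiv,
    "max": np.maximum,
    "min": np.minimum,
}


class MalformedTreeError(ValueError):
    pass


def validate_tree(tree: Tree, n_vars: int | None = None) -> None:
    """Raise :class:`MalformedTreeError` unless the tree is well-formed."""
    if not isinstance(tree, tuple) or not tree:
        raise MalformedTreeError(f"not a tree node: {tree!r}")
    head = tree[0]
    if head == "var":
        if len(tree) != 2 or not isinstance(tree[1], int) or tree[1] < 0:
            raise MalformedTreeError(f"bad variable node: {tree!r}")
        if n_vars is not None and tree[1] >= n_vars:
            raise MalformedTreeError(f"variable index out of range: {tree!r}")
    elif head == "const":
        if len(tree) != 2 or not np.isfinite(tree[1]):
            raise MalformedTreeError(f"bad constant node: {tree!r}")
    elif head in _OP_FN:
        if len(tree) != 3:
            raise MalformedTreeError(f"operator {head!r} needs 2 children")
        validate_tree(tree[1], n_vars)
        validate_tree(tree[2], n_vars)
    else:
        raise MalformedTreeError(f"unknown node head {head!r}")


def eval_tree(tree: Tree, X: np.ndarray) -> np.ndarray:
    """Vectorized evaluation; ``X`` is (n_samples, n_vars)."""
    head = tree[0]
    if head == "var":
        return X[:, tree[1]].astype(float)
    if head == "const":
        return np.full(X.shape[0], float(tree[1]))
    fn = _OP_FN.get(head)
    if fn is None:
        raise MalformedTreeError(f"unknown node head {head!r}")
    return fn(eval_tree(tree[1], X), eval_tree(tree[2], X))


def eval_point(tree: Tree, features: Sequence[float]) -> float:
    """Evaluate at a single feature vector."""
    return float(eval_tree(tree, np.asarray(features, dtype=float)[None, :])[0])


# ---------------------------------------------------------------------------
# parsing and rendering

_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z_0-9]*|[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?|[(),*/+-])")

_INFIX_OPS = {"+": "add", "-": "sub", "*": "mul", "/": "div"}


def parse_expression(
    text: str, variables: Sequence[str] = ("X0", "X1", "X2"), aliases: dict[str, int] | None = None
) -> Tree:
    """Parse a prefix expression string like ``mul(max(X0, X1), X2)``.

    Variable tokens may be any name in ``variables`` (index = position) or
    in ``aliases`` (name -> index); ``BP``, ``CC`` and ``MF`` are accepted
    as built-in aliases for X0..X2 when three variables are in play.
    """
    var_index = {name: i for i, name in enumerate(variables)}
    if aliases:
        var_index.update(aliases)
    if len(variables) == 3:
        for i, alias in enumerate(("BP", "CC", "MF")):
            var_index.setdefault(alias, i)

    tokens = _TOKEN.findall(text)
    if "".join(_TOKEN.sub("", text).split()):
        raise ValueError(f"cannot tokenize expression: {text!r}")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take(expected: str | None = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"unexpected end of expression in {text!r}")
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise ValueError(f"expected {expected!r}, got {tok!r} in {text!r}")
        pos += 1
        return tok

    def parse_node() -> Tree:
        tok = take()
        if tok in OPERATORS and peek() == "(":
            take("(")
            left = parse_node()
            take(",")
            right = parse_node()
            take(")")
            return (tok, left, right)
        if tok in var_index:
            return ("var", var_index[tok])
        try:
            return ("const", float(tok))
        except ValueError:
            raise ValueError(f"unknown token {tok!r} in {text!r}") from None

    tree = parse_node()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in expression {text!r}")
    return tree


def render_prefix(tree: Tree, variables: Sequence[str] | None = None) -> str:
    head = tree[0]
    if head == "var":
        return variables[tree[1]] if variables else f"X{tree[1]}"
    if head == "const":
        return repr(round(float(tree[1]), 6))
    left = render_prefix(tree[1], variables)
    right = render_prefix(tree[2], variables)
    return f"{head}({left}, {right})"


_INFIX_SYMBOL = {"add": "+", "sub": "-", "mul": "*", "div": "/"}


def render_infix(tree: Tree, variables: Sequence[str] | None = None) -> str:
    head = tree[0]
    if head == "var":
        return variables[tree[1]] if variables else f"X{tree[1]}"
    if head == "const":
        return repr(round(float(tree[1]), 6))
    left = render_infix(tree[1], variables)
    right = render_infix(tree[2], variables)
    if head in _INFIX_SYMBOL:
        return f"({left} {_INFIX_SYMBOL[head]} {right})"
    return f"{head}({left}, {right})"


def tree_to_json(tree: Tree) -> str:
    return json.dumps(tree)


def tree_from_json(text: str) -> Tree:
    def fix(node):
        if isinstance(node, list):
            return tuple(fix(x) for x in node)
        return node

    tree = fix(json.loads(text))
    validate_tree(tree)
    return tree


def tree_to_dot(tree: Tree, variables: Sequence[str] | None = None) -> str:
    """DOT digraph for rendering an expression tree."""
    lines = ["digraph expression {", "  node [shape=box];"]
    counter = [0]

    def emit(node: Tree) -> int:
        idx = counter[0]
        counter[0] += 1
        head = node[0]
        if head == "var":
            label = variables[node[1]] if variables else f"X{node[1]}"
        elif head == "const":
            label = repr(round(float(node[1]), 6))
        else:
            label = head
        lines.append(f'  n{idx} [label="{label}"];')
        if head not in ("var", "const"):
            for child in node[1:]:
                cidx = emit(child)
                lines.append(f"  n{idx} -> n{cidx};")
        return idx

    emit(tree)
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# analysis

def count_nodes(tree: Tree) -> int:
    if tree[0] in ("var", "const"):
        return 1
    return 1 + count_nodes(tree[1]) + count_nodes(tree[2])


def tree_depth(tree: Tree) -> int:
    if tree[0] in ("var", "const"):
        return 0
    return 1 + max(tree_depth(tree[1]), tree_depth(tree[2]))


def variable_counts(tree: Tree) -> dict[int, int]:
    counts: dict[int, int] = {}

    def walk(node: Tree) -> None:
        if node[0] == "var":
            counts[node[1]] = counts.get(node[1], 0) + 1
        elif node[0] != "const":
            walk(node[1])
            walk(node[2])

    walk(tree)
    return counts


def variable_frequencies(tree: Tree, n_vars: int = 3) -> dict[int, float]:
    """Each variable's share of variable-leaf occurrences (sums to 1 when
    any variable occurs; all zero for constant-only trees)."""
    counts = variable_counts(tree)
    total = sum(counts.values())
    if total == 0:
        return {i: 0.0 for i in range(n_vars)}
    return {i: counts.get(i, 0) / total for i in range(n_vars)}


# ---------------------------------------------------------------------------
# simplification

def _fold_const(head: str, a: float, b: float) -> float:
    if head == "div":
        return 1.0 if abs(b) <= DIV_EPS else a / b
    return {
        "add": a + b,
        "sub": a - b,
        "mul": a * b,
        "max": max(a, b),
        "min": min(a, b),
    }[head]


def _is_const(node: Tree, value: float | None = None) -> bool:
    return node[0] == "const" and (value is None or node[1] == value)


def _simplify_once(tree: Tree) -> Tree:
    if tree[0] in ("var", "const"):
        return tree
    head, a, b = tree[0], _simplify_once(tree[1]), _simplify_once(tree[2])
    if _is_const(a) and _is_const(b):
        return ("const", _fold_const(head, a[1], b[1]))
    if head == "add":
        if _is_const(a, 0.0):
            return b
        if _is_const(b, 0.0):
            return a
    elif head == "sub":
        if _is_const(b, 0.0):
            return a
        if a == b:
            return ("const", 0.0)
    elif head == "mul":
        if _is_const(a, 1.0):
            return b
        if _is_const(b, 1.0):
            return a
        if _is_const(a, 0.0) or _is_const(b, 0.0):
            return ("const", 0.0)
    elif head == "div":
        if _is_const(b) and abs(b[1]) <= DIV_EPS:
            return ("const", 1.0)
        if _is_const(b, 1.0):
            return a
    elif head in ("max", "min"):
        if a == b:
            return a
    return (head, a, b)


def simplify_tree(tree: Tree) -> Tree:
    """Conservative semantics-preserving rewriting to a fixed point.

    Rules: constant folding (with protected-division semantics), additive
    and multiplicative identities and annihilators, x - x = 0, and max/min
    idempotence.  No distribution laws are applied, so every rewrite is an
    exact pointwise equality.
    """
    while True:
        new = _simplify_once(tree)
        if new == tree:
            return new
        tree = new


def trees_equivalent(
    a: Tree, b: Tree, n_vars: int = 3, n_probes: int = 1000,
    tol: float = 1e-9, seed: int = 0,
) -> bool:
    """Random-probe pointwise equality on the unit cube."""
    rng = np.random.default_rng(seed)
    X = rng.random((n_probes, n_vars))
    return bool(np.all(np.abs(eval_tree(a, X) - eval_tree(b, X)) <= tol))
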