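"""Expression trees mapping genotype rows to a raw numeric output.

A tree is stored as a flat list of nodes in prefix (Polish) order, the same
layout genetic-programming systems use: subtree boundaries are computable by
an arity walk, which makes subtree crossover and mutation cheap.  Terminals
are feature references ``X1..Xm`` (0-based ``feature`` index internally) and
the integer constants 0, 1, 2.  All operators are total functions: division
is protected (returns the numerator when the divisor is 0), modulo is safe
(returns 0 when the divisor is 0), and boolean operators coerce any nonzero
value to true and emit 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import CorruptTreeError, InvalidArgumentError

TREE_SCHEMA_VERSION = 1


def _protected_div(a, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(b != 0, np.divide(a, np.where(b != 0, b, 1.0)), a)


def _safe_mod(a, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(b != 0, np.mod(a, np.where(b != 0, b, 1.0)), 0.0)


def _b(x):
    return x != 0


# name -> (arity, vectorized implementation over float64 arrays)
OPERATORS: dict[str, tuple[int, object]] = {
    "ADD": (2, lambda a, b: a + b),
    "SUB": (2, lambda a, b: a - b),
    "MUL": (2, lambda a, b: a * b),
    "DIV": (2, _protected_div),
    "MIN": (2, np.minimum),
    "MAX": (2, np.maximum),
    "MOD": (2, _safe_mod),
    "EQ": (2, lambda a, b: (a == b).astype(np.float64)),
    "GT": (2, lambda a, b: (a > b).astype(np.float64)),
    "LT": (2, lambda a, b: (a < b).astype(np.float64)),
    "AND": (2, lambda a, b: (_b(a) & _b(b)).astype(np.float64)),
    "OR": (2, lambda a, b: (_b(a) | _b(b)).astype(np.float64)),
    "XOR": (2, lambda a, b: (_b(a) ^ _b(b)).astype(np.float64)),
    "NOT": (1, lambda a: (a == 0).astype(np.float64)),
}

TERMINAL_CONSTANTS = (0, 1, 2)


@dataclass(frozen=True)
class Node:
    """One prefix-order tree node: an operator, feature ref, or constant."""

    kind: str  # "op" | "feat" | "const"
    value: object

    @property
    def arity(self) -> int:
        if self.kind == "op":
            try:
                return OPERATORS[self.value][0]
            except KeyError as exc:
                raise CorruptTreeError(f"unknown operator {self.value!r}") from exc
        return 0

    def label(self) -> str:
        if self.kind == "feat":
            return f"X{self.value + 1}"
        return str(self.value)


class ExpressionTree:
    """A prefix-order program over genotype features.

    ``nodes[0]`` is the root; ``size`` is the node count and the GP's
    tree-length objective.
    """

    __slots__ = ("nodes",)

    def __init__(self, nodes: list[Node]):
        if not nodes:
            raise CorruptTreeError("empty tree")
        self.nodes = list(nodes)
        self._validate()

    def _validate(self) -> None:
        need = 1
        for node in self.nodes:
            if need <= 0:
                raise CorruptTreeError("dangling nodes after complete tree")
            if node.kind == "op" and node.value not in OPERATORS:
                raise CorruptTreeError(f"unknown operator {node.value!r}")
            if node.kind not in ("op", "feat", "const"):
                raise CorruptTreeError(f"unknown node kind {node.kind!r}")
            need += node.arity - 1
        if need != 0:
            raise CorruptTreeError("truncated tree (missing arguments)")

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def depth(self) -> int:
        stack = [0]
        best = 0
        for node in self.nodes:
            d = stack.pop()
            best = max(best, d)
            stack.extend([d + 1] * node.arity)
        return best

    def feature_indices(self) -> set[int]:
        """Indices of every feature terminal appearing in the program."""
        return {n.value for n in self.nodes if n.kind == "feat"}

    def subtree_slice(self, begin: int) -> slice:
        """Prefix-order extent of the subtree rooted at position ``begin``."""
        end = begin + 1
        need = self.nodes[begin].arity
        while need > 0:
            need += self.nodes[end].arity - 1
            end += 1
        return slice(begin, end)

    def to_prefix_str(self) -> str:
        # readable s-expression, mainly for logs and reprs
        out: list[str] = []

        def emit(i: int = 0) -> int:
            node = self.nodes[i]
            if node.arity == 0:
                out.append(node.label())
                return i + 1
            out.append(f"({node.label()}")
            j = i + 1
            for _ in range(node.arity):
                out.append(" ")
                j = emit(j)
            out.append(")")
            return j

        emit(0)
        return "".join(out)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ExpressionTree({self.to_prefix_str()})"

    def signature(self) -> tuple:
        """Hashable identity used for fitness caching."""
        return tuple((n.kind, n.value) for n in self.nodes)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": TREE_SCHEMA_VERSION,
                "nodes": [[n.kind, n.value] for n in self.nodes],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ExpressionTree":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CorruptTreeError(f"malformed tree JSON: {exc}") from exc
        if not isinstance(obj, dict) or "schema_version" not in obj:
            raise CorruptTreeError("tree JSON missing schema_version")
        if obj["schema_version"] != TREE_SCHEMA_VERSION:
            raise CorruptTreeError(
                f"unsupported tree schema version {obj['schema_version']!r}"
            )
        try:
            nodes = [Node(kind, value) for kind, value in obj["nodes"]]
        except (TypeError, ValueError, KeyError) as exc:
            raise CorruptTreeError(f"malformed node list: {exc}") from exc
        return cls(nodes)


def evaluate_tree(tree: ExpressionTree, genotypes: np.ndarray) -> np.ndarray:
    """Apply the program row-wise; returns a float64 vector of length n.

    Total on all inputs by construction of the operator set.
    """
    X = np.asarray(genotypes, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidArgumentError("genotypes must be 2-D")
    n, m = X.shape
    feats = tree.feature_indices()
    if feats and max(feats) >= m:
        raise InvalidArgumentError(
            f"tree references feature X{max(feats) + 1} but matrix has m={m}"
        )
    stack: list[np.ndarray] = []
    for node in reversed(tree.nodes):
        if node.kind == "feat":
            stack.append(X[:, node.value])
        elif node.kind == "const":
            stack.append(np.full(n, float(node.value)))
        else:
            arity, fn = OPERATORS[node.value]
            args = [stack.pop() for _ in range(arity)]
            stack.append(np.asarray(fn(*args), dtype=np.float64))
    return stack.pop()


# -- random generation and variation (GP primitives) ----------------------


def random_tree(
    rng: np.random.Generator,
    n_features: int,
    min_depth: int = 2,
    max_depth: int = 4,
    grow: bool | None = None,
) -> ExpressionTree:
    """Ramped half-and-half style generator.

    ``grow=False`` builds a full tree to the sampled depth; ``grow=True``
    may place terminals early.  ``grow=None`` flips a coin (the ramped
    half-and-half initialization).
    """
    if n_features < 1:
        raise InvalidArgumentError("n_features must be >= 1")
    depth = int(rng.integers(min_depth, max_depth + 1))
    use_grow = bool(rng.integers(2)) if grow is None else grow
    op_names = list(OPERATORS)
    nodes: list[Node] = []

    def build(d: int) -> None:
        at_bottom = d >= depth
        make_terminal = at_bottom or (use_grow and d >= 1 and rng.random() < 0.3)
        if make_terminal:
            # features favoured over constants 3:1 so programs read genotypes
            if rng.random() < 0.75:
                nodes.append(Node("feat", int(rng.integers(n_features))))
            else:
                nodes.append(Node("const", int(rng.choice(TERMINAL_CONSTANTS))))
            return
        name = op_names[int(rng.integers(len(op_names)))]
        nodes.append(Node("op", name))
        for _ in range(OPERATORS[name][0]):
            build(d + 1)

    build(0)
    return ExpressionTree(nodes)


def subtree_crossover(
    a: ExpressionTree,
    b: ExpressionTree,
    rng: np.random.Generator,
    max_depth: int,
) -> tuple[ExpressionTree, ExpressionTree]:
    """One-point subtree exchange; offspring deeper than ``max_depth``
    are replaced by the corresponding parent."""
    ia = int(rng.integers(a.size))
    ib = int(rng.integers(b.size))
    sa, sb = a.subtree_slice(ia), b.subtree_slice(ib)
    child_a = ExpressionTree(a.nodes[: sa.start] + b.nodes[sb] + a.nodes[sa.stop:])
    child_b = ExpressionTree(b.nodes[: sb.start] + a.nodes[sa] + b.nodes[sb.stop:])
    if child_a.depth > max_depth:
        child_a = ExpressionTree(a.nodes)
    if child_b.depth > max_depth:
        child_b = ExpressionTree(b.nodes)
    return child_a, child_b


def subtree_mutation(
    tree: ExpressionTree,
    rng: np.random.Generator,
    n_features: int,
    max_depth: int,
) -> ExpressionTree:
    """Replace a uniformly chosen subtree with a freshly grown one."""
    i = int(rng.integers(tree.size))
    s = tree.subtree_slice(i)
    repl = random_tree(rng, n_features, min_depth=0, max_depth=2, grow=True)
    child = ExpressionTree(tree.nodes[: s.start] + repl.nodes + tree.nodes[s.stop:])
    if child.depth > max_depth:
        return ExpressionTree(tree.nodes)
    return child
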