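"""Flexible neural trees (FNTs).

An FNT is a tree-structured neural model: leaves are input variables and
internal nodes are *flexible neuron operators* — weighted sums of their
children passed through a parameterised Gaussian,

    net = sum_j w_j * o_j,      out = exp(-((net - a) / b) ** 2),

where ``a`` (center) and ``b`` (width) are node parameters.  The operator
output always lies in ``(0, 1]`` for finite inputs, so a tree whose root is
an operator yields a probability-like score directly usable at a 0.5
decision threshold.

This module holds the representation, evaluation (scalar and row-batched),
structural validation, complexity measures and a parenthesised s-expression
serialization, e.g. ``(+2 w=0.5,0.5 a=0.3 b=0.4 (c1) (c2))``.  Variables are
0-based internally and rendered 1-based (``c1``..``cn``) in all I/O.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, List, Tuple, Union

import numpy as np

#: Smallest admissible |width|; the Gaussian divides by b.
B_FLOOR = 1e-6

#: Operator arities the evolved trees draw from.
DEFAULT_ARITIES = frozenset({2, 3, 4, 5})


class TreeError(ValueError):
    """Base class for FNT errors."""


class DegenerateParameterError(TreeError):
    """An operator width fell below :data:`B_FLOOR`."""


class TreeValidationError(TreeError):
    """A structural invariant of the tree is violated."""


class ParseError(TreeError):
    """Malformed s-expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class VariableNode:
    """Leaf referring to input variable ``index`` (0-based)."""

    index: int

    @property
    def children(self) -> tuple:
        return ()

    def copy(self) -> "VariableNode":
        return VariableNode(self.index)


@dataclass
class OperatorNode:
    """Flexible neuron operator: Gaussian of the weighted child sum."""

    weights: List[float]
    center: float
    width: float
    children: List["Node"]

    @property
    def arity(self) -> int:
        return len(self.children)

    def copy(self) -> "OperatorNode":
        return OperatorNode(
            list(self.weights),
            self.center,
            self.width,
            [c.copy() for c in self.children],
        )


Node = Union[VariableNode, OperatorNode]


@dataclass
class FlexibleNeuralTree:
    """An FNT over ``n_inputs`` variables.

    Parameters
    ----------
    root
        Root node; an :class:`OperatorNode` unless ``require_operator_root``
        is disabled (the default rule keeps the model output in ``(0, 1]``).
    n_inputs
        Width of the input vectors the tree accepts.
    operator_arities
        Arities internal nodes may take.
    max_depth
        Depth cap; a single operator over leaves has depth 1.
    """

    root: Node
    n_inputs: int
    operator_arities: frozenset = DEFAULT_ARITIES
    max_depth: int = 4
    require_operator_root: bool = True

    def evaluate(self, input_vector) -> float:
        return evaluate_tree(self, input_vector)

    def evaluate_batch(self, X) -> np.ndarray:
        return evaluate_tree_batch(self, X)

    def copy(self) -> "FlexibleNeuralTree":
        return FlexibleNeuralTree(
            self.root.copy(),
            self.n_inputs,
            self.operator_arities,
            self.max_depth,
            self.require_operator_root,
        )

    def serialize(self) -> str:
        return serialize_tree(self)


def iter_nodes(node: Node) -> Iterator[Node]:
    """Pre-order traversal."""
    yield node
    for child in node.children:
        yield from iter_nodes(child)


def node_depth(node: Node) -> int:
    if isinstance(node, VariableNode):
        return 0
    return 1 + max(node_depth(c) for c in node.children)


def tree_complexity(tree: FlexibleNeuralTree) -> Tuple[int, int]:
    """Return ``(node_count, depth)``; one operator over leaves has depth 1."""
    count = sum(1 for _ in iter_nodes(tree.root))
    return count, node_depth(tree.root)


def evaluate_node(node: Node, input_vector) -> float:
    """Evaluate ``node`` on a single input vector.

    A leaf returns its variable's value; an operator returns the Gaussian of
    the weighted sum of its children's outputs.
    """
    if isinstance(node, VariableNode):
        if not 0 <= node.index < len(input_vector):
            raise TreeValidationError(
                f"variable index {node.index} out of range for input of "
                f"length {len(input_vector)}"
            )
        return float(input_vector[node.index])
    if abs(node.width) < B_FLOOR:
        raise DegenerateParameterError(
            f"operator width |b|={abs(node.width)!r} below floor {B_FLOOR}"
        )
    net = 0.0
    for w, child in zip(node.weights, node.children):
        net += w * evaluate_node(child, input_vector)
    z = (net - node.center) / node.width
    return math.exp(-z * z)


def evaluate_tree(tree: FlexibleNeuralTree, input_vector) -> float:
    """Evaluate the tree on one input vector of length ``n_inputs``."""
    if len(input_vector) != tree.n_inputs:
        raise TreeValidationError(
            f"input length {len(input_vector)} != n_inputs {tree.n_inputs}"
        )
    return evaluate_node(tree.root, input_vector)


def _eval_batch(node: Node, X: np.ndarray) -> np.ndarray:
    if isinstance(node, VariableNode):
        return X[:, node.index]
    if abs(node.width) < B_FLOOR:
        raise DegenerateParameterError(
            f"operator width |b|={abs(node.width)!r} below floor {B_FLOOR}"
        )
    net = node.weights[0] * _eval_batch(node.children[0], X)
    for w, child in zip(node.weights[1:], node.children[1:]):
        net = net + w * _eval_batch(child, X)
    z = (net - node.center) / node.width
    return np.exp(-z * z)


def evaluate_tree_batch(tree: FlexibleNeuralTree, X) -> np.ndarray:
    """Vectorised evaluation over the rows of ``X`` (shape ``(n, n_inputs)``)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != tree.n_inputs:
        raise TreeValidationError(
            f"expected shape (n, {tree.n_inputs}), got {X.shape}"
        )
    for node in iter_nodes(tree.root):
        if isinstance(node, VariableNode) and not 0 <= node.index < tree.n_inputs:
            raise TreeValidationError(
                f"variable index {node.index} out of range (n_inputs="
                f"{tree.n_inputs})"
            )
    return _eval_batch(tree.root, X)


def validate_tree(tree: FlexibleNeuralTree) -> List[str]:
    """Check every invariant; return a list of violations (empty iff valid).

    Violations name the offending node by path (``root``, ``root.0``,
    ``root.0.2`` ... child positions) and the rule broken.  This reports and
    never raises.
    """
    violations: List[str] = []

    if tree.require_operator_root and not isinstance(tree.root, OperatorNode):
        violations.append("root: root must be an operator node")

    def visit(node: Node, path: str) -> None:
        if isinstance(node, VariableNode):
            if not 0 <= node.index < tree.n_inputs:
                violations.append(
                    f"{path}: variable index {node.index} out of range "
                    f"[0, {tree.n_inputs})"
                )
            return
        if len(node.weights) != len(node.children):
            violations.append(
                f"{path}: {len(node.weights)} weights for "
                f"{len(node.children)} children"
            )
        arity = len(node.children)
        if arity not in tree.operator_arities:
            violations.append(
                f"{path}: arity {arity} not in allowed set "
                f"{sorted(tree.operator_arities)}"
            )
        if not 2 <= arity <= 5:
            violations.append(f"{path}: arity {arity} outside [2, 5]")
        if abs(node.width) < B_FLOOR:
            violations.append(
                f"{path}: width |b|={abs(node.width)!r} below floor {B_FLOOR}"
            )
        for i, child in enumerate(node.children):
            visit(child, f"{path}.{i}")

    visit(tree.root, "root")
    depth = node_depth(tree.root)
    if depth > tree.max_depth:
        violations.append(
            f"root: depth {depth} exceeds max_depth {tree.max_depth}"
        )
    return violations


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _serialize_node(node: Node) -> str:
    if isinstance(node, VariableNode):
        return f"(c{node.index + 1})"
    w = ",".join(repr(float(x)) for x in node.weights)
    parts = [
        f"+{node.arity}",
        f"w={w}",
        f"a={float(node.center)!r}",
        f"b={float(node.width)!r}",
    ]
    parts.extend(_serialize_node(c) for c in node.children)
    return "(" + " ".join(parts) + ")"


def serialize_tree(tree: FlexibleNeuralTree) -> str:
    """Render the tree as a parenthesised s-expression.

    Parameters are written with :func:`repr`, which round-trips IEEE doubles
    exactly, so deserialization reproduces the tree bit-for-bit.
    """
    return _serialize_node(tree.root)


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str):
    pos = 0
    tokens = []
    for match in _TOKEN.finditer(text):
        if text[pos:match.start()].strip():
            raise ParseError("unexpected characters", pos)
        tokens.append((match.group(), match.start()))
        pos = match.end()
    if text[pos:].strip():
        raise ParseError("unexpected trailing characters", pos)
    return tokens


def _parse_node(tokens, i: int) -> Tuple[Node, int]:
    if i >= len(tokens):
        raise ParseError("unexpected end of input", tokens[-1][1] if tokens else 0)
    tok, pos = tokens[i]
    if tok != "(":
        raise ParseError(f"expected '(', got {tok!r}", pos)
    i += 1
    if i >= len(tokens):
        raise ParseError("unexpected end of input after '('", pos)
    head, hpos = tokens[i]
    if head.startswith("c") and re.fullmatch(r"c\d+", head):
        index = int(head[1:]) - 1
        if index < 0:
            raise ParseError("variable indices are 1-based", hpos)
        i += 1
        if i >= len(tokens) or tokens[i][0] != ")":
            raise ParseError("expected ')' after variable", hpos)
        return VariableNode(index), i + 1
    m = re.fullmatch(r"\+(\d+)", head)
    if not m:
        raise ParseError(f"expected '+<arity>' or 'c<index>', got {head!r}", hpos)
    arity = int(m.group(1))
    i += 1
    fields = {}
    while i < len(tokens) and "=" in tokens[i][0]:
        key, _, value = tokens[i][0].partition("=")
        fields[key] = (value, tokens[i][1])
        i += 1
    for key in ("w", "a", "b"):
        if key not in fields:
            raise ParseError(f"operator missing field {key!r}", hpos)
    try:
        weights = [float(x) for x in fields["w"][0].split(",")]
    except ValueError:
        raise ParseError("malformed weight list", fields["w"][1]) from None
    try:
        center = float(fields["a"][0])
        width = float(fields["b"][0])
    except ValueError:
        raise ParseError("malformed numeric field", fields["a"][1]) from None
    children: List[Node] = []
    while i < len(tokens) and tokens[i][0] == "(":
        child, i = _parse_node(tokens, i)
        children.append(child)
    if i >= len(tokens) or tokens[i][0] != ")":
        raise ParseError("expected ')'", tokens[i - 1][1])
    if len(children) != arity:
        raise ParseError(
            f"operator +{arity} has {len(children)} children", hpos
        )
    if len(weights) != arity:
        raise ParseError(
            f"operator +{arity} has {len(weights)} weights", hpos
        )
    return OperatorNode(weights, center, width, children), i + 1


def deserialize_tree(
    text: str,
    n_inputs: int,
    operator_arities: frozenset = DEFAULT_ARITIES,
    max_depth: int = 4,
    allow_leaf_root: bool = False,
) -> FlexibleNeuralTree:
    """Parse an s-expression produced by :func:`serialize_tree`.

    With ``allow_leaf_root`` a bare variable such as ``(c1)`` is accepted at
    the root; under the default root-operator rule it raises.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty input", 0)
    root, i = _parse_node(tokens, 0)
    if i != len(tokens):
        raise ParseError("trailing tokens after tree", tokens[i][1])
    if isinstance(root, VariableNode) and not allow_leaf_root:
        raise ParseError("root must be an operator node", tokens[0][1])
    tree = FlexibleNeuralTree(
        root,
        n_inputs,
        operator_arities,
        max_depth,
        require_operator_root=not allow_leaf_root,
    )
    problems = validate_tree(tree)
    if problems:
        raise TreeValidationError("; ".join(problems))
    return tree
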