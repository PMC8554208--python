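"""Evolutionary training of flexible neural trees.

Structure is searched with a genetic-programming loop (tournament selection,
subtree crossover, four mutation kinds, elitism) and the continuous
parameters ``(w, a, b)`` of each generation's champion are refined by
simulated annealing under a geometric cooling schedule.  Fitness is the RMSE
between the tree output and the 0/1 labels plus a small parsimony penalty
proportional to node count; lower is better.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the config, so a (config, seed) pair reproduces the run
exactly, including the serialized champion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .tree import (
    B_FLOOR,
    FlexibleNeuralTree,
    Node,
    OperatorNode,
    VariableNode,
    evaluate_tree_batch,
    iter_nodes,
    node_depth,
    tree_complexity,
)


class EvolutionError(ValueError):
    pass


@dataclass
class EvolutionConfig:
    """Settings for the hybrid GP + simulated-annealing search.

    The defaults are a desk-scale budget that reliably learns the small
    (nine-input) meta-learning problems this model is built for; every value
    is overridable.
    """

    population_size: int = 50
    generations: int = 100
    max_depth: int = 4
    crossover_rate: float = 0.8
    mutation_rate: float = 0.3
    tournament_size: int = 3
    sa_initial_temp: float = 0.02
    sa_cooling: float = 0.97
    sa_steps_per_temp: int = 15
    sa_min_temp: float = 1e-4
    sa_step_scale: float = 20.0
    sa_cycles: int = 3
    parsimony_coefficient: float = 1e-3
    operator_arities: Tuple[int, ...] = (2, 3, 4, 5)
    n_inputs: int = 9
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise EvolutionError("population_size must be >= 2")
        if self.generations < 1:
            raise EvolutionError("generations must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise EvolutionError(f"{name} must lie in [0, 1]")
        if not self.operator_arities:
            raise EvolutionError("operator_arities must be nonempty")
        if not set(self.operator_arities) <= {2, 3, 4, 5}:
            raise EvolutionError("operator arities must lie in {2..5}")
        if self.sa_min_temp >= self.sa_initial_temp:
            raise EvolutionError("sa_min_temp must be < sa_initial_temp")
        if self.sa_initial_temp <= 0 or self.sa_min_temp <= 0:
            raise EvolutionError("SA temperatures must be positive")
        if not 0.0 < self.sa_cooling < 1.0:
            raise EvolutionError("sa_cooling must lie in (0, 1)")
        if self.parsimony_coefficient < 0:
            raise EvolutionError("parsimony_coefficient must be >= 0")


@dataclass
class EvolutionResult:
    """Outcome of :func:`evolve`.

    ``history`` records (best, mean) population fitness per generation; with
    elitism the best column is non-increasing.
    """

    best_tree: FlexibleNeuralTree
    best_fitness: float
    history: List[Tuple[float, float]]
    evaluations: int


# ---------------------------------------------------------------------------
# Random trees
# ---------------------------------------------------------------------------

def _random_leaf(n_inputs: int, rng: np.random.Generator) -> VariableNode:
    return VariableNode(int(rng.integers(n_inputs)))


def _random_operator_params(arity: int, rng: np.random.Generator):
    weights = list(rng.uniform(-1.0, 1.0, size=arity))
    center = float(rng.uniform(0.0, 1.0))
    width = float(rng.uniform(0.1, 1.0))
    return weights, center, width


def _grow(n_inputs, arities, max_depth, depth, rng) -> Node:
    # Leaf probability rises linearly with depth; forced leaf at the cap.
    if depth >= max_depth or (depth > 0 and rng.random() < depth / max_depth):
        return _random_leaf(n_inputs, rng)
    arity = int(rng.choice(arities))
    weights, center, width = _random_operator_params(arity, rng)
    children = [
        _grow(n_inputs, arities, max_depth, depth + 1, rng)
        for _ in range(arity)
    ]
    return OperatorNode(weights, center, width, children)


def random_tree(
    n_inputs: int,
    operator_arities,
    max_depth: int,
    rng: np.random.Generator,
) -> FlexibleNeuralTree:
    """Grow a random valid tree (operator root, depth <= ``max_depth``).

    Weights are Uniform(-1, 1), centers Uniform(0, 1) and widths
    Uniform(0.1, 1); each child becomes a leaf with probability increasing
    linearly in depth and always at the depth cap.
    """
    arities = sorted(set(operator_arities))
    if not arities:
        raise EvolutionError("operator_arities must be nonempty")
    root = _grow(n_inputs, arities, max_depth, 0, rng)
    return FlexibleNeuralTree(
        root, n_inputs, frozenset(arities), max_depth
    )


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _nodes_with_slots(root: Node):
    """All (parent, child_index, node, level) triples; root has parent None."""
    out = [(None, -1, root, 0)]
    stack = [(root, 0)]
    while stack:
        node, level = stack.pop()
        for i, child in enumerate(node.children):
            out.append((node, i, child, level + 1))
            stack.append((child, level + 1))
    return out


def _truncate_to_depth(node: Node, budget: int, n_inputs: int, rng) -> Node:
    """Replace operators that exceed the remaining depth budget with leaves."""
    if isinstance(node, VariableNode):
        return node
    if budget <= 0:
        return _random_leaf(n_inputs, rng)
    node.children = [
        _truncate_to_depth(c, budget - 1, n_inputs, rng) for c in node.children
    ]
    return node


def crossover(
    parent1: FlexibleNeuralTree,
    parent2: FlexibleNeuralTree,
    rng: np.random.Generator,
) -> Tuple[FlexibleNeuralTree, FlexibleNeuralTree]:
    """Exchange uniformly chosen subtrees between copies of the parents.

    If the receiving slot is a root, only operator subtrees are eligible (the
    root-operator rule); offspring exceeding ``max_depth`` are repaired by
    truncating too-deep subtrees to random leaves.  The parents are left
    untouched.
    """
    if parent1.n_inputs != parent2.n_inputs:
        raise EvolutionError("parents must share n_inputs")
    c1, c2 = parent1.copy(), parent2.copy()
    slots1 = _nodes_with_slots(c1.root)
    slots2 = _nodes_with_slots(c2.root)
    i1 = int(rng.integers(len(slots1)))
    i2 = int(rng.integers(len(slots2)))
    par1, idx1, sub1, _ = slots1[i1]
    par2, idx2, sub2, _ = slots2[i2]
    if par1 is None and isinstance(sub2, VariableNode):
        ops = [s for s in slots2 if isinstance(s[2], OperatorNode)]
        par2, idx2, sub2, _ = ops[int(rng.integers(len(ops)))]
    if par2 is None and isinstance(sub1, VariableNode):
        ops = [s for s in slots1 if isinstance(s[2], OperatorNode)]
        par1, idx1, sub1, _ = ops[int(rng.integers(len(ops)))]

    if par1 is None:
        c1.root = sub2
    else:
        par1.children[idx1] = sub2
    if par2 is None:
        c2.root = sub1
    else:
        par2.children[idx2] = sub1

    for child in (c1, c2):
        child.root = _truncate_to_depth(
            child.root, child.max_depth, child.n_inputs, rng
        )
    return c1, c2


_MUTATION_KINDS = ("subtree", "leaf_index", "arity", "jitter")


def mutate(
    tree: FlexibleNeuralTree, rng: np.random.Generator
) -> FlexibleNeuralTree:
    """Return a mutated copy; one of four equiprobable kinds is applied.

    (i) replace a random subtree with a fresh random one, (ii) re-point a
    leaf at a different variable, (iii) change an operator's arity (children
    and weights padded or truncated), (iv) Gaussian jitter of a single
    node's ``(w, a, b)``.
    """
    out = tree.copy()
    arities = sorted(tree.operator_arities)
    kind = _MUTATION_KINDS[int(rng.integers(4))]
    slots = _nodes_with_slots(out.root)

    if kind == "subtree":
        parent, idx, node, level = slots[int(rng.integers(len(slots)))]
        if parent is None:
            out.root = random_tree(
                out.n_inputs, arities, out.max_depth, rng
            ).root
        else:
            parent.children[idx] = _grow(
                out.n_inputs, arities, out.max_depth, level, rng
            )
    elif kind == "leaf_index":
        leaves = [s for s in slots if isinstance(s[2], VariableNode)]
        if leaves:
            _, _, leaf, _ = leaves[int(rng.integers(len(leaves)))]
            if out.n_inputs > 1:
                choices = [i for i in range(out.n_inputs) if i != leaf.index]
                leaf.index = int(rng.choice(choices))
    elif kind == "arity":
        ops = [s for s in slots if isinstance(s[2], OperatorNode)]
        parent, idx, op, level = ops[int(rng.integers(len(ops)))]
        new_arity = int(rng.choice(arities))
        if new_arity < op.arity:
            op.children = op.children[:new_arity]
            op.weights = op.weights[:new_arity]
        else:
            while op.arity < new_arity:
                op.children.append(_random_leaf(out.n_inputs, rng))
                op.weights.append(float(rng.uniform(-1.0, 1.0)))
    else:  # jitter
        ops = [s for s in slots if isinstance(s[2], OperatorNode)]
        _, _, op, _ = ops[int(rng.integers(len(ops)))]
        scale = 0.1
        op.weights = [w + float(rng.normal(0, scale)) for w in op.weights]
        op.center += float(rng.normal(0, scale))
        new_width = op.width + float(rng.normal(0, scale))
        if abs(new_width) < 1e-3:
            new_width = math.copysign(1e-3, new_width if new_width != 0 else 1.0)
        op.width = new_width
    return out


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def fitness(
    tree: FlexibleNeuralTree,
    C: np.ndarray,
    y: np.ndarray,
    parsimony_coefficient: float = 0.0,
) -> float:
    """RMSE of tree output against ``y`` plus a parsimony penalty.

    ``parsimony_coefficient * node_count`` discourages bloat; with a zero
    coefficient a tree reproducing ``y`` exactly scores 0.
    """
    C = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    if C.ndim != 2 or C.shape[0] != y.shape[0]:
        raise EvolutionError(
            f"confidence matrix shape {C.shape} incompatible with "
            f"{y.shape[0]} labels"
        )
    out = evaluate_tree_batch(tree, C)
    rmse = float(np.sqrt(np.mean((out - y) ** 2)))
    if parsimony_coefficient:
        rmse += parsimony_coefficient * tree_complexity(tree)[0]
    return rmse


# ---------------------------------------------------------------------------
# Simulated annealing on the parameters of a fixed structure
# ---------------------------------------------------------------------------

def _collect_params(root: Node):
    """Flat list of (node, field, weight_index) for every tunable scalar."""
    params = []
    for node in iter_nodes(root):
        if isinstance(node, OperatorNode):
            for j in range(len(node.weights)):
                params.append((node, "w", j))
            params.append((node, "a", None))
            params.append((node, "b", None))
    return params


def _get_param(node, fieldname, j):
    if fieldname == "w":
        return node.weights[j]
    return node.center if fieldname == "a" else node.width


def _set_param(node, fieldname, j, value):
    if fieldname == "w":
        node.weights[j] = value
    elif fieldname == "a":
        node.center = value
    else:
        node.width = value


class _CachedEvaluator:
    """Per-node output cache so a one-parameter move re-evaluates only the
    perturbed node and its ancestors."""

    def __init__(self, root: Node, X: np.ndarray):
        self.X = X
        self.parent = {}
        self.out = {}
        for node in iter_nodes(root):
            for child in node.children:
                self.parent[id(child)] = node
        self._full(root)
        self.root = root

    def _full(self, node: Node) -> np.ndarray:
        if isinstance(node, VariableNode):
            vec = self.X[:, node.index]
        else:
            net = node.weights[0] * self._full(node.children[0])
            for w, child in zip(node.weights[1:], node.children[1:]):
                net = net + w * self._full(child)
            z = (net - node.center) / node.width
            vec = np.exp(-z * z)
        self.out[id(node)] = vec
        return vec

    def _recompute_one(self, node: OperatorNode) -> None:
        net = node.weights[0] * self.out[id(node.children[0])]
        for w, child in zip(node.weights[1:], node.children[1:]):
            net = net + w * self.out[id(child)]
        z = (net - node.center) / node.width
        self.out[id(node)] = np.exp(-z * z)

    def update_chain(self, node: OperatorNode):
        """Recompute ``node`` and its ancestors; return saved old outputs."""
        saved = []
        current = node
        while current is not None:
            saved.append((current, self.out[id(current)]))
            self._recompute_one(current)
            current = self.parent.get(id(current))
        return saved

    def restore(self, saved) -> None:
        for node, vec in saved:
            self.out[id(node)] = vec

    def root_output(self) -> np.ndarray:
        return self.out[id(self.root)]


def anneal_parameters(
    tree: FlexibleNeuralTree,
    C: np.ndarray,
    y: np.ndarray,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> FlexibleNeuralTree:
    """Refine ``(w, a, b)`` of every node by simulated annealing.

    Structure is untouched.  Each step perturbs one uniformly chosen scalar
    with a Gaussian of scale ``sa_step_scale * temperature``; improving moves
    are always accepted, worsening ones with probability ``exp(-delta / T)``.
    The temperature is multiplied by ``sa_cooling`` after
    ``sa_steps_per_temp`` steps until it drops below ``sa_min_temp``.  The
    best parameter vector ever seen is restored at the end, so the returned
    fitness never exceeds the input fitness.
    """
    C = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    out = tree.copy()
    params = _collect_params(out.root)
    if not params:
        return out
    n_params = len(params)
    penalty = config.parsimony_coefficient * tree_complexity(out)[0]

    cache = _CachedEvaluator(out.root, C)

    def current_fitness() -> float:
        diff = cache.root_output() - y
        return float(np.sqrt(np.mean(diff * diff))) + penalty

    fit = current_fitness()
    best_fit = fit
    best_params = [_get_param(n, f, j) for n, f, j in params]

    for _cycle in range(max(1, config.sa_cycles)):
        # Reannealing: each cycle reheats to the initial temperature and
        # resumes from the best parameters found so far.
        if _cycle:
            for (n, f, jj), value in zip(params, best_params):
                _set_param(n, f, jj, value)
            cache._full(out.root)
            fit = best_fit
        temp = config.sa_initial_temp
        while temp >= config.sa_min_temp:
            for _ in range(config.sa_steps_per_temp):
                node, fieldname, j = params[int(rng.integers(n_params))]
                delta = float(rng.normal(0.0, config.sa_step_scale * temp))
                old = _get_param(node, fieldname, j)
                new = old + delta
                if fieldname == "b" and abs(new) < B_FLOOR:
                    continue
                _set_param(node, fieldname, j, new)
                saved = cache.update_chain(node)
                new_fit = current_fitness()
                dv = new_fit - fit
                if dv <= 0 or rng.random() < math.exp(-dv / temp):
                    fit = new_fit
                    if fit < best_fit:
                        best_fit = fit
                        best_params = [
                            _get_param(n, f, jj) for n, f, jj in params
                        ]
                else:
                    _set_param(node, fieldname, j, old)
                    cache.restore(saved)
            temp *= config.sa_cooling

    for (node, fieldname, j), value in zip(params, best_params):
        _set_param(node, fieldname, j, value)
    return out


# ---------------------------------------------------------------------------
# The generational loop
# ---------------------------------------------------------------------------

def _tournament(
    fitnesses: List[float],
    sizes: List[int],
    k: int,
    rng: np.random.Generator,
) -> int:
    """Pick the best of ``k`` random entrants; ties go to the smaller tree,
    then to the earlier index."""
    entrants = rng.integers(len(fitnesses), size=k)
    best = None
    for i in entrants:
        i = int(i)
        key = (fitnesses[i], sizes[i], i)
        if best is None or key < best:
            best = key
    return best[2]


def evolve(
    C: np.ndarray, y: np.ndarray, config: Optional[EvolutionConfig] = None
) -> EvolutionResult:
    """Search for the FNT minimising :func:`fitness` on ``(C, y)``.

    Generational GP with elitism; simulated annealing polishes each
    generation's champion.  Raises if ``y`` contains a single class (the
    regression target would be degenerate).
    """
    config = config or EvolutionConfig()
    config.validate()
    C = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    if C.ndim != 2 or C.shape[1] != config.n_inputs:
        raise EvolutionError(
            f"expected confidence matrix with {config.n_inputs} columns, "
            f"got shape {C.shape}"
        )
    if C.shape[0] != y.shape[0] or C.shape[0] < 2:
        raise EvolutionError("need >= 2 rows with matching labels")
    if len(np.unique(y)) < 2:
        raise EvolutionError("labels contain a single class")

    rng = np.random.default_rng(config.seed)
    arities = sorted(set(config.operator_arities))
    pc = config.parsimony_coefficient

    population = [
        random_tree(config.n_inputs, arities, config.max_depth, rng)
        for _ in range(config.population_size)
    ]
    fitnesses = [fitness(t, C, y, pc) for t in population]
    evaluations = len(population)
    sizes = [tree_complexity(t)[0] for t in population]

    history: List[Tuple[float, float]] = []
    best_tree = None
    best_fit = math.inf

    for _generation in range(config.generations):
        champ_idx = min(
            range(len(population)),
            key=lambda i: (fitnesses[i], sizes[i], i),
        )
        # One reannealing cycle per generation: successive champion
        # polishes across generations already act as restarts.
        champion = anneal_parameters(
            population[champ_idx], C, y, replace(config, sa_cycles=1), rng
        )
        champ_fit = fitness(champion, C, y, pc)
        evaluations += 1
        if champ_fit <= fitnesses[champ_idx]:
            population[champ_idx] = champion
            fitnesses[champ_idx] = champ_fit

        if fitnesses[champ_idx] < best_fit:
            best_fit = fitnesses[champ_idx]
            best_tree = population[champ_idx].copy()
        history.append((best_fit, float(np.mean(fitnesses))))

        offspring = [best_tree.copy()]
        while len(offspring) < config.population_size:
            i = _tournament(fitnesses, sizes, config.tournament_size, rng)
            j = _tournament(fitnesses, sizes, config.tournament_size, rng)
            if rng.random() < config.crossover_rate:
                k1, k2 = crossover(population[i], population[j], rng)
            else:
                k1, k2 = population[i].copy(), population[j].copy()
            for child in (k1, k2):
                if rng.random() < config.mutation_rate:
                    child = mutate(child, rng)
                if len(offspring) < config.population_size:
                    offspring.append(child)
        population = offspring
        fitnesses = [fitness(t, C, y, pc) for t in population]
        evaluations += len(population)
        sizes = [tree_complexity(t)[0] for t in population]

    champ_idx = min(
        range(len(population)), key=lambda i: (fitnesses[i], sizes[i], i)
    )
    if fitnesses[champ_idx] < best_fit:
        best_fit = fitnesses[champ_idx]
        best_tree = population[champ_idx].copy()

    return EvolutionResult(
        best_tree=best_tree,
        best_fitness=best_fit,
        history=history,
        evaluations=evaluations,
    )
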