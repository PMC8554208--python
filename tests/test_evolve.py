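"""Evolutionary search: variation operators, fitness, SA, the full loop."""

import numpy as np
import pytest

from fntstack.evolve import (
    EvolutionConfig,
    EvolutionError,
    anneal_parameters,
    crossover,
    evolve,
    fitness,
    mutate,
    random_tree,
)
from fntstack.tree import (
    FlexibleNeuralTree,
    OperatorNode,
    VariableNode,
    evaluate_tree_batch,
    iter_nodes,
    node_depth,
    serialize_tree,
    tree_complexity,
    validate_tree,
)


class TestRandomTree:
    def test_depth_one_forces_leaf_children(self, rng):
        for _ in range(20):
            tree = random_tree(9, (2, 3, 4, 5), 1, rng)
            assert isinstance(tree.root, OperatorNode)
            assert all(
                isinstance(c, VariableNode) for c in tree.root.children
            )

    def test_same_seed_same_tree(self):
        t1 = random_tree(9, (2, 3), 4, np.random.default_rng(7))
        t2 = random_tree(9, (2, 3), 4, np.random.default_rng(7))
        assert serialize_tree(t1) == serialize_tree(t2)

    def test_all_trees_valid(self, rng):
        for _ in range(200):
            tree = random_tree(9, (2, 3, 4, 5), 4, rng)
            assert validate_tree(tree) == []

    def test_variable_coverage_over_many_draws(self, rng):
        seen = set()
        for _ in range(10_000):
            tree = random_tree(9, (2, 3, 4, 5), 3, rng)
            seen.update(
                n.index for n in iter_nodes(tree.root)
                if isinstance(n, VariableNode)
            )
            if len(seen) == 9:
                break
        assert seen == set(range(9))

    def test_empty_arity_set_rejected(self, rng):
        with pytest.raises(EvolutionError):
            random_tree(9, (), 4, rng)


def _node_kinds(tree):
    out = []
    for n in iter_nodes(tree.root):
        if isinstance(n, VariableNode):
            out.append(("leaf", n.index))
        else:
            out.append(("op", len(n.children)))
    return sorted(out)


class TestCrossover:
    def test_children_valid_over_many_pairs(self, rng):
        for _ in range(300):
            p1 = random_tree(9, (2, 3), 3, rng)
            p2 = random_tree(9, (2, 3), 3, rng)
            c1, c2 = crossover(p1, p2, rng)
            assert validate_tree(c1) == []
            assert validate_tree(c2) == []

    def test_parents_unmodified(self, rng):
        p1 = random_tree(9, (2, 3, 4), 4, rng)
        p2 = random_tree(9, (2, 3, 4), 4, rng)
        s1, s2 = serialize_tree(p1), serialize_tree(p2)
        crossover(p1, p2, rng)
        assert serialize_tree(p1) == s1
        assert serialize_tree(p2) == s2

    def test_node_conservation_without_depth_repair(self, rng):
        # shallow parents cannot trigger the depth repair, so the node
        # multiset of the offspring equals that of the parents
        for _ in range(200):
            p1 = random_tree(9, (2, 3), 2, rng)
            p2 = random_tree(9, (2, 3), 2, rng)
            p1.max_depth = p2.max_depth = 4
            c1, c2 = crossover(p1, p2, rng)
            assert sorted(_node_kinds(c1) + _node_kinds(c2)) == sorted(
                _node_kinds(p1) + _node_kinds(p2)
            )

    def test_mismatched_inputs_rejected(self, rng):
        p1 = random_tree(9, (2,), 2, rng)
        p2 = random_tree(4, (2,), 2, rng)
        with pytest.raises(EvolutionError):
            crossover(p1, p2, rng)


class TestMutate:
    def test_output_always_valid(self, rng):
        tree = random_tree(9, (2, 3, 4, 5), 4, rng)
        for _ in range(1000):
            tree2 = mutate(tree, rng)
            assert validate_tree(tree2) == []
            assert node_depth(tree2.root) <= tree2.max_depth

    def test_reproducible_under_frozen_rng(self, rng):
        tree = random_tree(9, (2, 3), 4, rng)
        m1 = mutate(tree, np.random.default_rng(3))
        m2 = mutate(tree, np.random.default_rng(3))
        assert serialize_tree(m1) == serialize_tree(m2)

    def test_input_tree_unmodified(self, rng):
        tree = random_tree(9, (2, 3), 4, rng)
        before = serialize_tree(tree)
        for _ in range(50):
            mutate(tree, rng)
        assert serialize_tree(tree) == before


class TestFitness:
    def test_perfect_tree_scores_zero(self, worked_fixture):
        tree, inputs, expected = worked_fixture
        y = np.asarray(expected)
        assert fitness(tree, inputs, y) == pytest.approx(0.0, abs=1e-15)

    def test_constant_one_tree_on_all_negative_labels(self):
        # operator with zero weights, center=net=0, width 1 -> output 1
        tree = FlexibleNeuralTree(
            OperatorNode([0.0, 0.0], 0.0, 1.0, [VariableNode(0), VariableNode(1)]),
            n_inputs=9,
        )
        C = np.random.default_rng(0).uniform(0, 1, (20, 9))
        assert fitness(tree, C, np.zeros(20)) == pytest.approx(1.0)

    def test_hand_computed_rmse(self, worked_fixture):
        tree, inputs, expected = worked_fixture
        y = np.array([1.0, 0.0, 1.0, 0.0])
        resid = np.asarray(expected) - y
        want = np.sqrt(np.mean(resid**2))
        assert fitness(tree, inputs, y) == pytest.approx(want, abs=1e-12)

    def test_parsimony_penalty_counts_nodes(self, worked_fixture):
        tree, inputs, expected = worked_fixture
        y = np.asarray(expected)
        assert fitness(tree, inputs, y, 1e-3) == pytest.approx(5e-3, abs=1e-12)

    def test_dimension_mismatch_raises(self, worked_fixture):
        tree, inputs, _ = worked_fixture
        with pytest.raises(EvolutionError):
            fitness(tree, inputs, np.zeros(3))


class TestAnnealParameters:
    def test_structure_unchanged_and_never_worse(self, rng):
        C = rng.uniform(0, 1, (50, 9))
        y = (C[:, 0] > 0.5).astype(float)
        config = EvolutionConfig(sa_steps_per_temp=5, sa_cycles=1)
        for _ in range(5):
            tree = random_tree(9, (2, 3), 3, rng)
            before = fitness(tree, C, y, config.parsimony_coefficient)
            after_tree = anneal_parameters(tree, C, y, config, rng)
            after = fitness(after_tree, C, y, config.parsimony_coefficient)
            assert after <= before + 1e-12
            assert _node_kinds(after_tree) == _node_kinds(tree) or [
                k for k in _node_kinds(after_tree) if k[0] == "op"
            ] == [k for k in _node_kinds(tree) if k[0] == "op"]

    def test_recovers_known_operator_parameters(self):
        # data generated from a known single-operator tree; SA from a random
        # start must recover an equivalent parameterisation
        true = FlexibleNeuralTree(
            OperatorNode([0.8, -0.5], 0.2, 0.6, [VariableNode(0), VariableNode(1)]),
            n_inputs=9,
        )
        gen = np.random.default_rng(0)
        C = gen.uniform(0, 1, (200, 9))
        y = evaluate_tree_batch(true, C)
        r = np.random.default_rng(0)
        init = FlexibleNeuralTree(
            OperatorNode(
                list(r.uniform(-1, 1, 2)),
                float(r.uniform(0, 1)),
                float(r.uniform(0.1, 1)),
                [VariableNode(0), VariableNode(1)],
            ),
            n_inputs=9,
        )
        config = EvolutionConfig(parsimony_coefficient=0.0)
        fitted = anneal_parameters(init, C, y, config, np.random.default_rng(0))
        assert fitness(fitted, C, y) < 0.05


class TestEvolve:
    def test_history_best_is_non_increasing(self, rng, lean_evolution_config):
        C = rng.uniform(0, 1, (60, 9))
        y = (C[:, 2] > 0.6).astype(int)
        result = evolve(C, y, lean_evolution_config)
        best = [h[0] for h in result.history]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_same_seed_same_champion(self, rng, lean_evolution_config):
        C = rng.uniform(0, 1, (40, 9))
        y = (C[:, 0] > 0.5).astype(int)
        r1 = evolve(C, y, lean_evolution_config)
        r2 = evolve(C, y, lean_evolution_config)
        assert serialize_tree(r1.best_tree) == serialize_tree(r2.best_tree)
        assert r1.best_fitness == r2.best_fitness

    def test_champion_is_valid(self, rng, lean_evolution_config):
        C = rng.uniform(0, 1, (40, 9))
        y = (C[:, 1] > 0.5).astype(int)
        result = evolve(C, y, lean_evolution_config)
        assert validate_tree(result.best_tree) == []

    def test_single_class_labels_rejected(self, rng, lean_evolution_config):
        C = rng.uniform(0, 1, (20, 9))
        with pytest.raises(EvolutionError):
            evolve(C, np.ones(20), lean_evolution_config)

    def test_config_validation(self):
        with pytest.raises(EvolutionError):
            EvolutionConfig(population_size=1).validate()
        with pytest.raises(EvolutionError):
            EvolutionConfig(sa_min_temp=2.0).validate()
        with pytest.raises(EvolutionError):
            EvolutionConfig(operator_arities=(6,)).validate()
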