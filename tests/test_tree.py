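"""Decision-tree rollback, path enumeration, validation, and comparison."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_ev, brute_force_paths, random_chance_tree
from copdad.tree import (
    COMPLEMENT,
    ConfigurationError,
    Edge,
    Recommendation,
    Strategy,
    TreeNode,
    TreeValidationError,
    enumerate_paths,
    recommend,
    rollback,
    validate,
)


def three_level_tree():
    """Fixed 3-level tree with 8 leaves and arbitrary probabilities."""
    def pair(label, p, a, b):
        return TreeNode.chance(label, [("a", p, a), ("b", 1 - p, b)])

    leaves = [TreeNode.terminal(f"L{i}", v)
              for i, v in enumerate([0.0, 2.5, -1.0, 7.0, 3.3, 0.4, 9.9, 1.1])]
    mid = [
        pair("m0", 0.3, leaves[0], leaves[1]),
        pair("m1", 0.8, leaves[2], leaves[3]),
        pair("m2", 0.5, leaves[4], leaves[5]),
        pair("m3", 0.25, leaves[6], leaves[7]),
    ]
    top = [pair("t0", 0.6, mid[0], mid[1]), pair("t1", 0.1, mid[2], mid[3])]
    return pair("root", 0.45, top[0], top[1])


# expected value of three_level_tree, accumulated path by path
THREE_LEVEL_EXPECTED = (
    0.45 * 0.6 * (0.3 * 0.0 + 0.7 * 2.5)
    + 0.45 * 0.4 * (0.8 * -1.0 + 0.2 * 7.0)
    + 0.55 * 0.1 * (0.5 * 3.3 + 0.5 * 0.4)
    + 0.55 * 0.9 * (0.25 * 9.9 + 0.75 * 1.1)
)


class TestRollback:
    def test_terminal_identity(self):
        assert rollback(TreeNode.terminal("t", 3.2)) == 3.2

    def test_symmetric_chance(self):
        node = TreeNode.chance("c", [
            ("a", 0.5, TreeNode.terminal("a", 0.0)),
            ("b", 0.5, TreeNode.terminal("b", 2.0)),
        ])
        assert rollback(node) == pytest.approx(1.0)

    def test_three_level_tree_matches_hand_path_sum(self):
        assert rollback(three_level_tree()) == pytest.approx(
            THREE_LEVEL_EXPECTED, abs=1e-12
        )

    def test_decision_node_takes_maximum(self):
        node = TreeNode.decision("d", [
            ("worse", TreeNode.terminal("w", 1.0)),
            ("better", TreeNode.terminal("b", 4.0)),
        ])
        assert rollback(node) == 4.0

    def test_complement_edge_resolved(self):
        node = TreeNode.chance("c", [
            ("a", 0.3, TreeNode.terminal("a", 1.0)),
            ("b", COMPLEMENT, TreeNode.terminal("b", 3.0)),
        ])
        assert rollback(node) == pytest.approx(0.3 * 1.0 + 0.7 * 3.0)

    @pytest.mark.parametrize("probs", [(0.5, 0.6), (0.2, 0.2)])
    def test_bad_probability_sum_names_node(self, probs):
        node = TreeNode.chance("broken", [
            ("a", probs[0], TreeNode.terminal("a", 1.0)),
            ("b", probs[1], TreeNode.terminal("b", 2.0)),
        ])
        with pytest.raises(TreeValidationError, match="broken"):
            rollback(node)

    def test_negative_probability_rejected(self):
        node = TreeNode.chance("neg", [
            ("a", -0.1, TreeNode.terminal("a", 1.0)),
            ("b", 1.1, TreeNode.terminal("b", 2.0)),
        ])
        with pytest.raises(TreeValidationError):
            rollback(node)

    def test_decision_edge_with_probability_rejected(self):
        node = TreeNode.decision("d", [("a", TreeNode.terminal("a", 1.0))])
        node.children[0].probability = 0.5
        with pytest.raises(TreeValidationError, match="decision"):
            validate(node)

    def test_terminal_with_children_rejected(self):
        bad = TreeNode(kind="terminal", label="t", payoff=1.0,
                       children=[Edge("e", None, TreeNode.terminal("x", 0.0))])
        with pytest.raises(TreeValidationError, match="terminal"):
            validate(bad)


class TestEnumeratePaths:
    def test_single_terminal(self):
        assert enumerate_paths(TreeNode.terminal("t", 4.2)) == [(1.0, 4.2, [])]

    def test_single_chance_node(self):
        node = TreeNode.chance("c", [
            ("a", 0.3, TreeNode.terminal("a", 1.0)),
            ("b", 0.7, TreeNode.terminal("b", 2.0)),
        ])
        paths = enumerate_paths(node)
        assert sorted(p for p, _, _ in paths) == pytest.approx([0.3, 0.7])

    def test_nested_products(self):
        inner = TreeNode.chance("inner", [
            ("x", 0.25, TreeNode.terminal("x", 5.0)),
            ("y", 0.75, TreeNode.terminal("y", 1.0)),
        ])
        node = TreeNode.chance("outer", [
            ("a", 0.4, inner),
            ("b", 0.6, TreeNode.terminal("b", 0.0)),
        ])
        by_labels = {tuple(lbls): p for p, _, lbls in enumerate_paths(node)}
        assert by_labels[("a", "x")] == pytest.approx(0.4 * 0.25)
        assert by_labels[("a", "y")] == pytest.approx(0.4 * 0.75)
        assert by_labels[("b",)] == pytest.approx(0.6)

    def test_decision_node_rejected(self):
        node = TreeNode.decision("d", [("a", TreeNode.terminal("a", 1.0))])
        with pytest.raises(TreeValidationError, match="decision"):
            enumerate_paths(node)


class TestRandomTreeProperties:
    """Oracle equivalence and conservation on 200 seeded random trees."""

    def test_rollback_equals_brute_force_and_probabilities_conserve(self):
        rng = random.Random(12345)
        for _ in range(200):
            tree = random_chance_tree(rng)
            assert rollback(tree) == pytest.approx(brute_force_ev(tree), abs=1e-9)
            total = sum(p for p, _ in brute_force_paths(tree))
            assert total == pytest.approx(1.0, abs=1e-9)
            # package enumeration agrees with the independent one
            pkg = sum(p * v for p, v, _ in enumerate_paths(tree))
            assert pkg == pytest.approx(rollback(tree), abs=1e-9)

    def test_increasing_a_payoff_never_decreases_value(self):
        rng = random.Random(777)
        for _ in range(30):
            tree = random_chance_tree(rng, max_depth=4)
            before = rollback(tree)
            terminals = [n for n in tree.walk() if n.kind == "terminal"]
            victim = rng.choice(terminals)
            victim.payoff += rng.uniform(0.1, 3.0)
            assert rollback(tree) >= before - 1e-12


class TestRecommend:
    def _strat(self, name, value):
        return Strategy(name=name, root=TreeNode.terminal("t", value))

    def test_full_code_favored(self):
        rec = recommend([self._strat("Full Code", 5.0), self._strat("DNI", 4.26)])
        assert rec.delta_qaly == pytest.approx(0.74)
        assert rec.recommended == "Full Code"

    def test_equal_is_indifferent(self):
        rec = recommend([self._strat("Full Code", 2.0), self._strat("DNI", 2.0)])
        assert rec.recommended == "indifferent"

    def test_dni_favored(self):
        rec = recommend([self._strat("Full Code", 2.0), self._strat("DNI", 2.1)])
        assert rec.delta_qaly == pytest.approx(-0.1)
        assert rec.recommended == "DNI"

    def test_within_tolerance_is_indifferent(self):
        rec = recommend(
            [self._strat("Full Code", 2.0), self._strat("DNI", 2.005)],
            tolerance=0.01,
        )
        assert rec.recommended == "indifferent"

    def test_missing_strategy_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="DNI"):
            recommend([self._strat("Full Code", 1.0), self._strat("Other", 2.0)])

    def test_strategy_with_decision_node_rejected(self):
        root = TreeNode.decision("d", [("a", TreeNode.terminal("a", 1.0))])
        with pytest.raises(TreeValidationError, match="decision"):
            Strategy(name="Full Code", root=root).validate()


class TestSerialization:
    def test_yaml_round_trip_is_lossless(self):
        tree = three_level_tree()
        again = TreeNode.from_yaml(tree.to_yaml())
        assert again.to_dict() == tree.to_dict()
        assert rollback(again) == pytest.approx(rollback(tree))

    def test_complement_edges_survive_round_trip(self):
        node = TreeNode.chance("c", [
            ("a", 0.3, TreeNode.terminal("a", 1.0)),
            ("b", COMPLEMENT, TreeNode.terminal("b", 2.0)),
        ])
        again = TreeNode.from_yaml(node.to_yaml())
        assert again.children[1].probability == COMPLEMENT
        assert rollback(again) == pytest.approx(rollback(node))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    p=st.floats(min_value=0.0, max_value=1.0),
    a=st.floats(min_value=-100, max_value=100),
    b=st.floats(min_value=-100, max_value=100),
)
def test_two_leaf_chance_is_convex_combination(p, a, b):
    node = TreeNode.chance("c", [
        ("a", p, TreeNode.terminal("a", a)),
        ("b", COMPLEMENT, TreeNode.terminal("b", b)),
    ])
    value = rollback(node)
    assert min(a, b) - 1e-9 <= value <= max(a, b) + 1e-9
    assert value == pytest.approx(p * a + (1 - p) * b, abs=1e-9)
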