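"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from copdad.model import CopdScenario, ModelParameters
from copdad.params import fixture_parameters
from copdad.tree import COMPLEMENT, TreeNode


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    """The canonical stand-in parameter set (no jitter)."""
    return fixture_parameters(seed=0)


@pytest.fixture(params=["mild", "moderate", "severe"])
def scenario(request) -> CopdScenario:
    return CopdScenario(copd_severity=request.param)


# ---------------------------------------------------------------------------
# independent oracles (deliberately not using copdad.tree.rollback /
# enumerate_paths internals)
# ---------------------------------------------------------------------------

def brute_force_paths(node: TreeNode) -> list[tuple[float, float]]:
    """Exhaustive root-to-leaf enumeration: (path probability, payoff).

    Resolves complement edges itself; supports chance/terminal trees only.
    """
    out: list[tuple[float, float]] = []
    stack = [(node, 1.0)]
    while stack:
        n, prob = stack.pop()
        if n.kind == "terminal":
            out.append((prob, n.payoff))
            continue
        raw = [e.probability for e in n.children]
        partial = sum(p for p in raw if p not in (COMPLEMENT, None))
        for p, e in zip(raw, n.children):
            if p in (COMPLEMENT, None):
                p = 1.0 - partial
            stack.append((e.child, prob * p))
    return out


def brute_force_ev(node: TreeNode) -> float:
    """Expected payoff by exhaustive path enumeration."""
    return sum(p * payoff for p, payoff in brute_force_paths(node))


def random_chance_tree(
    rng: random.Random, max_depth: int = 5, _depth: int = 0
) -> TreeNode:
    """A random valid chance/terminal tree of bounded depth."""
    if _depth >= max_depth or (_depth > 0 and rng.random() < 0.35):
        return TreeNode.terminal(f"leaf{rng.randrange(10**6)}", rng.uniform(-5.0, 10.0))
    n = rng.randint(2, 4)
    weights = [rng.uniform(0.05, 1.0) for _ in range(n)]
    total = sum(weights)
    edges = []
    for i, w in enumerate(weights[:-1]):
        edges.append((f"e{i}", w / total,
                      random_chance_tree(rng, max_depth, _depth + 1)))
    # last edge as complement: the sum is exactly 1 by construction
    edges.append((f"e{n - 1}", COMPLEMENT,
                  random_chance_tree(rng, max_depth, _depth + 1)))
    return TreeNode.chance(f"c{_depth}", edges)
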