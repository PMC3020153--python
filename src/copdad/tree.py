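"""Generic decision-tree model and expected-value rollback.

A decision tree is a hierarchy of :class:`TreeNode` objects of three kinds:

``decision``
    A choice under the decision maker's control.  Its edges carry no
    probabilities; rollback takes the maximum over children.
``chance``
    An event outside the decision maker's control.  Each outgoing edge
    carries a probability; the probabilities must sum to 1.  Rollback takes
    the probability-weighted mean of the children.
``terminal``
    An outcome.  It carries a payoff (here: quality-adjusted life years)
    and has no children.

Everything COPD-specific lives in :mod:`copdad.model`; this module knows
nothing about advance directives beyond the two canonical strategy names
used by :func:`recommend`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator

import yaml

logger = logging.getLogger(__name__)

#: Tolerance for chance-node probability sums.
PROB_SUM_TOL = 1e-9

#: Default indifference tolerance (QALYs) for strategy comparison.
INDIFFERENCE_TOL = 1e-9

#: Sentinel edge probability: resolved to 1 minus the sum of the sibling
#: probabilities at validation time.  At most one edge per chance node.
COMPLEMENT = "complement"

DECISION = "decision"
CHANCE = "chance"
TERMINAL = "terminal"

FULL_CODE = "Full Code"
DNI = "DNI"
INDIFFERENT = "indifferent"


class TreeValidationError(ValueError):
    """A tree violates a structural or probability invariant."""


class ConfigurationError(ValueError):
    """Inputs to an operation are incomplete or inconsistent."""


@dataclass
class Edge:
    """A labelled branch from a parent node to a child subtree.

    ``probability`` is ``None`` on decision-node edges, a float on chance
    edges, or the :data:`COMPLEMENT` sentinel (resolved during validation).
    """

    label: str
    probability: float | str | None
    child: "TreeNode"


@dataclass
class TreeNode:
    kind: str
    label: str
    children: list[Edge] = field(default_factory=list)
    payoff: float | None = None

    # -- constructors -------------------------------------------------

    @staticmethod
    def terminal(label: str, payoff: float) -> "TreeNode":
        return TreeNode(kind=TERMINAL, label=label, payoff=float(payoff))

    @staticmethod
    def chance(label: str, edges: list[tuple[str, float | str, "TreeNode"]]) -> "TreeNode":
        return TreeNode(
            kind=CHANCE,
            label=label,
            children=[Edge(lbl, p, child) for lbl, p, child in edges],
        )

    @staticmethod
    def decision(label: str, edges: list[tuple[str, "TreeNode"]]) -> "TreeNode":
        return TreeNode(
            kind=DECISION,
            label=label,
            children=[Edge(lbl, None, child) for lbl, child in edges],
        )

    # -- traversal ----------------------------------------------------

    def walk(self) -> Iterator["TreeNode"]:
        """Yield this node and every descendant, depth first."""
        yield self
        for edge in self.children:
            yield from edge.child.walk()

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "label": self.label}
        if self.kind == TERMINAL:
            d["payoff"] = self.payoff
        else:
            d["children"] = [
                {"label": e.label, "probability": e.probability, "child": e.child.to_dict()}
                for e in self.children
            ]
        return d

    @staticmethod
    def from_dict(d: dict) -> "TreeNode":
        if d["kind"] == TERMINAL:
            return TreeNode.terminal(d["label"], d["payoff"])
        edges = [
            Edge(c["label"], c.get("probability"), TreeNode.from_dict(c["child"]))
            for c in d.get("children", [])
        ]
        return TreeNode(kind=d["kind"], label=d["label"], children=edges)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "TreeNode":
        return TreeNode.from_dict(yaml.safe_load(text))


def _resolved_probabilities(node: TreeNode) -> list[float]:
    """Resolve the COMPLEMENT sentinel and check the probability simplex."""
    raw = [e.probability for e in node.children]
    n_complement = sum(1 for p in raw if p == COMPLEMENT or p is None)
    if n_complement > 1:
        raise TreeValidationError(
            f"chance node {node.label!r}: more than one complement edge"
        )
    partial = sum(float(p) for p in raw if p not in (COMPLEMENT, None))
    probs: list[float] = []
    for p in raw:
        if p in (COMPLEMENT, None):
            comp = 1.0 - partial
            if comp < -PROB_SUM_TOL:
                raise TreeValidationError(
                    f"chance node {node.label!r}: complement edge would be "
                    f"negative ({comp:.3g})"
                )
            probs.append(max(comp, 0.0))
        else:
            probs.append(float(p))
    for p, e in zip(probs, node.children):
        if p < 0:
            raise TreeValidationError(
                f"chance node {node.label!r}, edge {e.label!r}: negative "
                f"probability {p}"
            )
        if p > 1 + PROB_SUM_TOL:
            raise TreeValidationError(
                f"chance node {node.label!r}, edge {e.label!r}: probability "
                f"{p} exceeds 1"
            )
    total = sum(probs)
    if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=PROB_SUM_TOL):
        raise TreeValidationError(
            f"chance node {node.label!r}: probabilities sum to {total!r}, not 1"
        )
    return probs


def validate(node: TreeNode) -> None:
    """Check all TreeNode invariants, raising TreeValidationError on the
    first violation; the message names the offending node."""
    if node.kind == TERMINAL:
        if node.children:
            raise TreeValidationError(f"terminal node {node.label!r} has children")
        if node.payoff is None:
            raise TreeValidationError(f"terminal node {node.label!r} has no payoff")
        return
    if not node.children:
        raise TreeValidationError(f"{node.kind} node {node.label!r} has no children")
    if node.kind == DECISION:
        for e in node.children:
            if e.probability is not None:
                raise TreeValidationError(
                    f"decision node {node.label!r}, edge {e.label!r}: "
                    f"decision edges carry no probabilities"
                )
    elif node.kind == CHANCE:
        _resolved_probabilities(node)
    else:
        raise TreeValidationError(f"node {node.label!r}: unknown kind {node.kind!r}")
    for e in node.children:
        validate(e.child)


def rollback(node: TreeNode, _validated: bool = False) -> float:
    """Expected QALYs of a (sub)tree.

    Terminal nodes return their payoff, chance nodes the probability-weighted
    mean of their children, decision nodes the maximum over children (ties
    resolve to the first-listed child, with a logged notice).
    """
    if not _validated:
        validate(node)
    if node.kind == TERMINAL:
        return float(node.payoff)  # type: ignore[arg-type]
    if node.kind == CHANCE:
        probs = _resolved_probabilities(node)
        return sum(
            p * rollback(e.child, _validated=True)
            for p, e in zip(probs, node.children)
        )
    # decision
    values = [rollback(e.child, _validated=True) for e in node.children]
    best = max(values)
    winners = [i for i, v in enumerate(values) if v == best]
    if len(winners) > 1:
        logger.info(
            "decision node %r: tie among %s; taking first-listed child %r",
            node.label,
            [node.children[i].label for i in winners],
            node.children[winners[0]].label,
        )
    return best


def enumerate_paths(node: TreeNode) -> list[tuple[float, float, list[str]]]:
    """All root-to-leaf paths as (path probability, payoff, edge labels).

    Only defined for fully resolved trees (no decision nodes), where path
    probabilities sum to 1 and sum(p * payoff) equals :func:`rollback`.
    """
    validate(node)
    out: list[tuple[float, float, list[str]]] = []

    def _rec(n: TreeNode, prob: float, labels: list[str]) -> None:
        if n.kind == TERMINAL:
            out.append((prob, float(n.payoff), labels))  # type: ignore[arg-type]
            return
        if n.kind == DECISION:
            raise TreeValidationError(
                f"enumerate_paths: decision node {n.label!r} in a resolved tree"
            )
        probs = _resolved_probabilities(n)
        for p, e in zip(probs, n.children):
            _rec(e.child, prob * p, labels + [e.label])

    _rec(node, 1.0, [])
    return out


@dataclass
class Strategy:
    """A fully resolved choice: a named tree containing no decision nodes."""

    name: str
    root: TreeNode

    def validate(self) -> None:
        validate(self.root)
        for n in self.root.walk():
            if n.kind == DECISION:
                raise TreeValidationError(
                    f"strategy {self.name!r} contains decision node {n.label!r}"
                )

    def expected_value(self) -> float:
        self.validate()
        return rollback(self.root, _validated=True)


@dataclass
class Recommendation:
    """Outcome of comparing the two advance-directive strategies."""

    ev_by_strategy: dict[str, float]
    delta_qaly: float  # Full Code minus DNI
    recommended: str  # FULL_CODE, DNI, or INDIFFERENT


def recommend(
    strategies: list[Strategy], tolerance: float = INDIFFERENCE_TOL
) -> Recommendation:
    """Compare the Full Code and DNI strategies by expected QALYs.

    ``delta_qaly`` is EV(Full Code) - EV(DNI); the recommendation follows
    its sign, with |delta| <= tolerance reported as indifferent.
    """
    ev = {s.name: s.expected_value() for s in strategies}
    for required in (FULL_CODE, DNI):
        if required not in ev:
            raise ConfigurationError(f"missing strategy {required!r}")
    delta = ev[FULL_CODE] - ev[DNI]
    if abs(delta) <= tolerance:
        recommended = INDIFFERENT
    elif delta > 0:
        recommended = FULL_CODE
    else:
        recommended = DNI
    return Recommendation(ev_by_strategy=ev, delta_qaly=delta, recommended=recommended)
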