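"""Probabilistic Boolean network data model and stochastic semantics.

A PBN assigns each node one or more Boolean predictor rules, each carrying a
selection probability (weight).  One synchronous update step selects, for
every node independently, one of its rules with probability proportional to
its weight and applies it.  A small per-node perturbation probability ``p``
additionally flips random nodes: whenever at least one node is perturbed the
network function is *not* applied that step and the next state is the current
state with exactly the perturbed nodes flipped.  With ``p > 0`` the resulting
Markov chain is irreducible and aperiodic and therefore has a unique
stationary distribution, which is what gets compared to steady-state protein
measurements.

Nodes held fixed by an experimental condition (inhibitor inputs, doxycycline,
receptor-site knockouts) are clamped: they are neither updated nor perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expr import Const, ExpressionError, Node, parse_expression

FLAGS = ("H", "L", "FIXED", "INPUT")

#: Fitting bounds on raw selection weights by priority flag: main-pathway
#: rules (H) may not drop below 0.5, crosstalk rules (L) may not exceed it.
FLAG_BOUNDS = {"H": (0.5, 1.0), "L": (0.0, 0.5)}


class ModelError(ValueError):
    """Raised for structurally invalid models or conditions."""


class SizeError(ModelError):
    """Raised when an exact computation is requested above the state-space cap.

    Networks above the cap must use the sampling estimator
    (:func:`pbnfit.steady.estimate_marginals`).
    """


@dataclass(frozen=True)
class BooleanRule:
    """One predictor function for a target node.

    Parameters
    ----------
    target : str
        Node updated by this rule.
    expression : str or parsed AST
        Boolean formula over parent node names (``AND``/``OR``/``NOT``,
        constants ``0``/``1``).
    weight : float
        Selection probability in [0, 1] (normalised per target at model
        construction).
    flag : {"H", "L", "FIXED", "INPUT"}
        Priority flag.  H/L rules are optimisable with bounds [0.5, 1] and
        [0, 0.5] on the raw weight; FIXED weights are left untouched by the
        fitter; INPUT marks constant rules of clampable input nodes.
    """

    target: str
    expression: Node
    weight: float = 1.0
    flag: str = "FIXED"

    def __post_init__(self):
        if isinstance(self.expression, str):
            object.__setattr__(self, "expression", parse_expression(self.expression))
        if self.flag not in FLAGS:
            raise ModelError(f"unknown flag {self.flag!r} (expected one of {FLAGS})")
        if not (0.0 <= self.weight <= 1.0):
            raise ModelError(f"rule weight {self.weight} outside [0, 1] for {self.target}")
        if self.flag == "INPUT" and self.parents:
            raise ModelError(f"INPUT rule for {self.target} must be constant")

    @property
    def parents(self) -> frozenset[str]:
        return self.expression.variables()

    def evaluate(self, state: Mapping[str, int]) -> int:
        """Boolean value of the rule expression under ``state``."""
        return self.expression.evaluate(state)


def evaluate_rule(rule: BooleanRule, state: Mapping[str, int]) -> int:
    """Evaluate one rule against a state mapping node name -> {0, 1}."""
    return rule.evaluate(state)


@dataclass(frozen=True)
class Condition:
    """A named experimental condition given as a set of node clamps."""

    name: str
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "clamps", dict(self.clamps))
        for node, value in self.clamps.items():
            if value not in (0, 1):
                raise ModelError(f"clamp value for {node} must be 0 or 1, got {value!r}")

    def merged(self, other: "Condition", name: str | None = None) -> "Condition":
        """Composition of two clamp sets (``other`` wins on overlap)."""
        clamps = {**self.clamps, **other.clamps}
        return Condition(name or f"{self.name}+{other.name}", clamps)


UNCONSTRAINED = Condition("unconstrained", {})


class PBNModel:
    """An independent, synchronous PBN with random perturbation.

    Per-target weights are normalised by their raw sum at construction, so
    they always form a selection distribution.  Within one target every
    H-flagged normalised weight must be at least every L-flagged one.
    """

    def __init__(self, rules: Iterable[BooleanRule], p: float = 0.001,
                 nodes: Sequence[str] | None = None):
        rules = list(rules)
        if not rules:
            raise ModelError("a model needs at least one rule")
        if not (0.0 <= p < 1.0):
            raise ModelError(f"perturbation probability p={p} outside [0, 1)")
        if nodes is None:
            seen: dict[str, None] = {}
            for rule in rules:
                seen.setdefault(rule.target, None)
            nodes = list(seen)
        self.nodes: tuple[str, ...] = tuple(nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ModelError("duplicate node names")
        self.p = float(p)

        by_target: dict[str, list[BooleanRule]] = {name: [] for name in self.nodes}
        for rule in rules:
            if rule.target not in node_set:
                raise ModelError(f"rule targets undeclared node {rule.target!r}")
            missing = rule.parents - node_set
            if missing:
                raise ModelError(
                    f"rule for {rule.target} references undeclared node(s) {sorted(missing)}")
            by_target[rule.target].append(rule)
        for name in self.nodes:
            if not by_target[name]:
                raise ModelError(f"node {name!r} has no rule")
            total = sum(r.weight for r in by_target[name])
            if total <= 0:
                raise ModelError(f"weights of node {name!r} sum to zero")
            by_target[name] = [replace(r, weight=r.weight / total) for r in by_target[name]]
            h = [r.weight for r in by_target[name] if r.flag == "H"]
            low = [r.weight for r in by_target[name] if r.flag == "L"]
            if h and low and min(h) < max(low) - 1e-9:
                raise ModelError(
                    f"node {name!r}: H-flag weight {min(h):.4f} below L-flag weight {max(low):.4f}")
        self.rules: dict[str, tuple[BooleanRule, ...]] = {
            name: tuple(by_target[name]) for name in self.nodes}

    # -- introspection -----------------------------------------------------

    def __repr__(self) -> str:
        n_rules = sum(len(v) for v in self.rules.values())
        return f"PBNModel({len(self.nodes)} nodes, {n_rules} rules, p={self.p})"

    def all_rules(self) -> list[BooleanRule]:
        return [rule for name in self.nodes for rule in self.rules[name]]

    def edges(self) -> set[tuple[str, str]]:
        """Distinct (source, target) dependencies across all rules."""
        out: set[tuple[str, str]] = set()
        for rule in self.all_rules():
            for parent in rule.parents:
                out.add((parent, rule.target))
        return out

    def free_parameters(self) -> list[tuple[str, int]]:
        """(target, rule index) of every optimisable (H/L-flagged) rule."""
        out = []
        for name in self.nodes:
            for i, rule in enumerate(self.rules[name]):
                if rule.flag in ("H", "L"):
                    out.append((name, i))
        return out

    def input_nodes(self) -> list[str]:
        return [name for name in self.nodes
                if all(r.flag == "INPUT" for r in self.rules[name])]

    def with_rules(self, new_rules: Iterable[BooleanRule], p: float | None = None) -> "PBNModel":
        return PBNModel(new_rules, p=self.p if p is None else p, nodes=self.nodes)

    # -- semantics ---------------------------------------------------------

    def default_state(self, condition: Condition = UNCONSTRAINED) -> np.ndarray:
        """All-zero state with clamps applied, ordered as ``self.nodes``."""
        state = np.zeros(len(self.nodes), dtype=np.uint8)
        return self.apply_clamps(state, condition)

    def apply_clamps(self, state: np.ndarray, condition: Condition) -> np.ndarray:
        state = np.asarray(state, dtype=np.uint8).copy()
        for node, value in condition.clamps.items():
            if node not in self.nodes:
                raise ModelError(f"condition {condition.name!r} clamps unknown node {node!r}")
            state[self.nodes.index(node)] = value
        return state

    def state_mapping(self, state: np.ndarray) -> dict[str, int]:
        return {name: int(bit) for name, bit in zip(self.nodes, state)}

    def step(self, state: np.ndarray, condition: Condition = UNCONSTRAINED,
             rng: np.random.Generator | None = None) -> np.ndarray:
        """One transition of the perturbed synchronous PBN chain.

        Draw an independent Bernoulli(p) perturbation indicator for every
        non-clamped node.  If any fires, the next state is the current one
        with exactly the perturbed nodes flipped (the network function is not
        applied); otherwise every non-clamped node picks one of its rules by
        weight and takes its value.  Clamped nodes never change.
        """
        rng = np.random.default_rng() if rng is None else rng
        state = np.asarray(state, dtype=np.uint8)
        clamped = set(condition.clamps)
        free_idx = [i for i, name in enumerate(self.nodes) if name not in clamped]
        nxt = state.copy()
        if free_idx:
            gamma = rng.random(len(free_idx)) < self.p
            if gamma.any():
                for flip, i in zip(gamma, free_idx):
                    if flip:
                        nxt[i] ^= 1
                return nxt
        mapping = self.state_mapping(state)
        for i in free_idx:
            name = self.nodes[i]
            rules = self.rules[name]
            if len(rules) == 1:
                rule = rules[0]
            else:
                u = rng.random()
                acc = 0.0
                rule = rules[-1]
                for candidate in rules:
                    acc += candidate.weight
                    if u < acc:
                        rule = candidate
                        break
            nxt[i] = rule.evaluate(mapping)
        return nxt

    def transition_matrix(self, condition: Condition = UNCONSTRAINED,
                          cap: int = 14) -> tuple[np.ndarray, list[str]]:
        """Exact one-step transition matrix over the non-clamped nodes.

        Returns the row-stochastic matrix ``P`` and the list of free nodes;
        state index bit ``j`` (least significant first) is the value of free
        node ``j``.  Marginalises exactly over rule selection and
        perturbation.  Memory/time grow as ``4**n_free``; above ``cap`` a
        :class:`SizeError` directs the caller to the sampling estimator.
        """
        for node in condition.clamps:
            if node not in self.nodes:
                raise ModelError(f"condition {condition.name!r} clamps unknown node {node!r}")
        free = [name for name in self.nodes if name not in condition.clamps]
        nf = len(free)
        if nf > cap:
            raise SizeError(
                f"{nf} non-clamped nodes exceeds the exact cap ({cap}); "
                "use the two-state sampling estimator instead")
        n_states = 1 << nf
        p = self.p
        no_pert = (1.0 - p) ** nf

        # perturbation kernel over XOR masks (mask 0 is the update branch)
        masks = np.arange(n_states)
        popcount = np.array([bin(m).count("1") for m in masks])
        kernel = p ** popcount * (1.0 - p) ** (nf - popcount)
        kernel[0] = 0.0

        P = np.zeros((n_states, n_states))
        base = {node: value for node, value in condition.clamps.items()}
        for i in range(n_states):
            mapping = dict(base)
            for j, name in enumerate(free):
                mapping[name] = (i >> j) & 1
            # per-node ON probability under synchronous rule selection
            dist = np.ones(1)
            for name in free:
                q = sum(r.weight * r.evaluate(mapping) for r in self.rules[name])
                dist = np.concatenate([dist * (1.0 - q), dist * q])
            P[i] = no_pert * dist
            P[i, i ^ masks] += kernel
        return P, free


def marginal_from_distribution(pi: np.ndarray, free: list[str], node: str) -> float:
    """P(node = 1) under a distribution over the free-node state space."""
    j = free.index(node)
    idx = (np.arange(len(pi)) >> j) & 1
    return float(pi[idx == 1].sum())
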