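"""Chance-node decision-tree engine and the two strategy trees.

Strategies
----------
``reconstruction``
    Base cost = surgical cost + residual. Sequelae (probability
    ``p_seq_operative``) put the patient in the sequelae class and add the
    osteoarthritis or meniscus complication cost per the arm's split.
    Independently, primary failure (``p_fail``) adds one extra surgical
    cost and shifts the activity distribution one class down. Patients
    with neither event realize the pooled operative distribution.

``conservative``
    Base cost = conservative cost + residual. Crossover to surgery
    (``p_crossover``) adds one surgical cost but leaves the conservative
    activity distribution unchanged; sequelae behave as in the surgical
    arm with the conservative split. Events are independent.

``residual_cost_*`` are per-arm additive calibration constants that close
the gap between this published tree structure and the published expected
arm costs (the original model's exact micro-structure is not public); set
them to 0 for the literal rollback.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .evidence import CLASSES, ActivityClass, ActivityDistribution
from .utilities import UtilityKey, shifted_distribution

__all__ = [
    "ModelParams",
    "TreeNode",
    "StrategyResult",
    "ValidationReport",
    "STRATEGIES",
    "build_strategy_tree",
    "validate",
    "rollback",
    "enumerate_paths",
    "run_strategies",
    "calibrate_residuals",
    "replace_params",
    "tree_to_dict",
    "tree_from_dict",
    "render_tree",
]

STRATEGIES = ("conservative", "reconstruction")

PROB_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """All branch probabilities, costs, and arm activity distributions."""

    p_fail: float
    p_crossover: float
    p_seq_operative: float
    p_seq_conservative: float
    split_oa_operative: float
    split_oa_conservative: float
    cost_surgical: float
    cost_conservative: float
    cost_oa: float
    cost_meniscus: float
    dist_operative: ActivityDistribution
    dist_conservative: ActivityDistribution
    residual_cost_operative: float = 0.0
    residual_cost_conservative: float = 0.0
    sequelae_class: ActivityClass = ActivityClass.II
    horizon_months: float = 90.0

    def __post_init__(self) -> None:
        probs = {
            "p_fail": self.p_fail,
            "p_crossover": self.p_crossover,
            "p_seq_operative": self.p_seq_operative,
            "p_seq_conservative": self.p_seq_conservative,
            "split_oa_operative": self.split_oa_operative,
            "split_oa_conservative": self.split_oa_conservative,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {p}")
        costs = {
            "cost_surgical": self.cost_surgical,
            "cost_conservative": self.cost_conservative,
            "cost_oa": self.cost_oa,
            "cost_meniscus": self.cost_meniscus,
        }
        for name, c in costs.items():
            if c < 0:
                raise ValueError(f"{name} must be non-negative: {c}")
        if self.horizon_months <= 0:
            raise ValueError(f"horizon_months must be positive: {self.horizon_months}")
        object.__setattr__(self, "sequelae_class", ActivityClass(self.sequelae_class))


def replace_params(params: ModelParams, **changes) -> ModelParams:
    """Copy of ``params`` with the given fields replaced (re-validated)."""
    unknown = set(changes) - {f.name for f in dataclasses.fields(ModelParams)}
    if unknown:
        raise ValueError(f"unknown model parameters: {sorted(unknown)}")
    return dataclasses.replace(params, **changes)


@dataclass
class TreeNode:
    """Chance or terminal node. Terminal payoffs carry the full path cost."""

    kind: str  # "chance" | "terminal"
    label: str = ""
    children: list[tuple[float, "TreeNode"]] = field(default_factory=list)
    payoff_cost: float = 0.0
    payoff_effect: float = 0.0
    activity_class: ActivityClass | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("chance", "terminal"):
            raise ValueError(f"node kind must be chance|terminal, got {self.kind!r}")


@dataclass(frozen=True)
class StrategyResult:
    """Expected (cost, effect) of one strategy from tree rollback."""

    strategy: str
    expected_cost: float
    expected_effect: float

    def __post_init__(self) -> None:
        if self.expected_cost < 0:
            raise ValueError(f"expected cost negative: {self.expected_cost}")
        # tolerate float round-off at the bounds, then clamp
        if not (-1e-9 <= self.expected_effect <= 1.0 + 1e-9):
            raise ValueError(f"expected effect out of [0,1]: {self.expected_effect}")
        object.__setattr__(
            self, "expected_effect", min(max(self.expected_effect, 0.0), 1.0)
        )


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...] = ()


def _class_fanout(
    dist: ActivityDistribution, key: UtilityKey, cost: float, label: str
) -> TreeNode:
    """Chance node over activity classes; terminals carry the class utility."""
    children = [
        (
            dist[c],
            TreeNode(
                kind="terminal",
                label=f"{label}/class_{c.name}",
                payoff_cost=cost,
                payoff_effect=key.mean(c),
                activity_class=c,
            ),
        )
        for c in CLASSES
    ]
    return TreeNode(kind="chance", label=label, children=children)


def _sequelae_terminal(
    params: ModelParams, key: UtilityKey, cost: float, label: str
) -> TreeNode:
    c = params.sequelae_class
    return TreeNode(
        kind="terminal",
        label=label,
        payoff_cost=cost,
        payoff_effect=key.mean(c),
        activity_class=c,
    )


def build_strategy_tree(
    params: ModelParams, key: UtilityKey, strategy: str
) -> TreeNode:
    """Build one strategy's chance tree (children in fixed declaration order)."""
    if strategy == "reconstruction":
        return _build_reconstruction(params, key)
    if strategy == "conservative":
        return _build_conservative(params, key)
    raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")


def _build_reconstruction(params: ModelParams, key: UtilityKey) -> TreeNode:
    base = params.cost_surgical + params.residual_cost_operative
    shifted = shifted_distribution(params.dist_operative)

    def seq_branch(comp_cost: float, tag: str) -> TreeNode:
        # failure still adds a revision surgery; effect is the sequelae class either way
        return TreeNode(
            kind="chance",
            label=f"sequelae/{tag}",
            children=[
                (
                    params.p_fail,
                    _sequelae_terminal(
                        params, key, base + comp_cost + params.cost_surgical,
                        f"sequelae/{tag}/failed",
                    ),
                ),
                (
                    1.0 - params.p_fail,
                    _sequelae_terminal(
                        params, key, base + comp_cost, f"sequelae/{tag}/healed"
                    ),
                ),
            ],
        )

    sequelae = TreeNode(
        kind="chance",
        label="sequelae",
        children=[
            (params.split_oa_operative, seq_branch(params.cost_oa, "osteoarthritis")),
            (1.0 - params.split_oa_operative, seq_branch(params.cost_meniscus, "meniscus")),
        ],
    )
    no_sequelae = TreeNode(
        kind="chance",
        label="no_sequelae",
        children=[
            (
                params.p_fail,
                _class_fanout(shifted, key, base + params.cost_surgical, "no_sequelae/failed"),
            ),
            (
                1.0 - params.p_fail,
                _class_fanout(params.dist_operative, key, base, "no_sequelae/healed"),
            ),
        ],
    )
    return TreeNode(
        kind="chance",
        label="reconstruction",
        children=[
            (params.p_seq_operative, sequelae),
            (1.0 - params.p_seq_operative, no_sequelae),
        ],
    )


def _build_conservative(params: ModelParams, key: UtilityKey) -> TreeNode:
    base = params.cost_conservative + params.residual_cost_conservative

    def crossover_split(extra_cost: float, make_leaf, tag: str) -> TreeNode:
        # crossover adds one surgical cost; the activity outcome is unchanged
        return TreeNode(
            kind="chance",
            label=tag,
            children=[
                (
                    params.p_crossover,
                    make_leaf(extra_cost + params.cost_surgical, f"{tag}/crossover"),
                ),
                (1.0 - params.p_crossover, make_leaf(extra_cost, f"{tag}/no_crossover")),
            ],
        )

    def seq_branch(comp_cost: float, tag: str) -> TreeNode:
        def make(extra: float, sub_tag: str) -> TreeNode:
            return _sequelae_terminal(params, key, base + comp_cost + extra, sub_tag)

        return crossover_split(0.0, make, f"sequelae/{tag}")

    sequelae = TreeNode(
        kind="chance",
        label="sequelae",
        children=[
            (params.split_oa_conservative, seq_branch(params.cost_oa, "osteoarthritis")),
            (
                1.0 - params.split_oa_conservative,
                seq_branch(params.cost_meniscus, "meniscus"),
            ),
        ],
    )

    def dist_leaf(extra: float, tag: str) -> TreeNode:
        return _class_fanout(params.dist_conservative, key, base + extra, tag)

    no_sequelae = crossover_split(0.0, dist_leaf, "no_sequelae")
    return TreeNode(
        kind="chance",
        label="conservative",
        children=[
            (params.p_seq_conservative, sequelae),
            (1.0 - params.p_seq_conservative, no_sequelae),
        ],
    )


def validate(tree: TreeNode) -> ValidationReport:
    """Check chance-node probability sums and terminal payoff finiteness.

    Returns a structured report naming every violating node; never raises
    on model content.
    """
    import math

    violations: list[str] = []

    def visit(node: TreeNode, path: str) -> None:
        where = path or node.label or "<root>"
        if node.kind == "chance":
            if not node.children:
                violations.append(f"{where}: chance node has no children")
                return
            total = 0.0
            for i, (p, child) in enumerate(node.children):
                if not (0.0 <= p <= 1.0):
                    violations.append(f"{where}: child {i} probability {p} out of [0,1]")
                total += p
                visit(child, f"{where}/{child.label or i}")
            if abs(total - 1.0) > PROB_TOL:
                violations.append(f"{where}: child probabilities sum to {total!r}, not 1")
        else:
            if not (math.isfinite(node.payoff_cost) and math.isfinite(node.payoff_effect)):
                violations.append(
                    f"{where}: non-finite payoff ({node.payoff_cost}, {node.payoff_effect})"
                )

    visit(tree, "")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def rollback(tree: TreeNode) -> tuple[float, float]:
    """Bottom-up expected (cost, effect) over the tree's chance nodes."""
    report = validate(tree)
    if not report.ok:
        raise ValueError("invalid tree: " + "; ".join(report.violations))
    return _rollback(tree)


def _rollback(node: TreeNode) -> tuple[float, float]:
    if node.kind == "terminal":
        return node.payoff_cost, node.payoff_effect
    cost = 0.0
    effect = 0.0
    for p, child in node.children:
        c, e = _rollback(child)
        cost += p * c
        effect += p * e
    return cost, effect


def enumerate_paths(tree: TreeNode) -> Iterator[tuple[float, float, float, str]]:
    """Exhaustive root-to-leaf paths: (probability, cost, effect, leaf label).

    Independent of :func:`rollback`; the expectation of the enumerated paths
    must equal the rollback result.
    """

    def walk(node: TreeNode, prob: float) -> Iterator[tuple[float, float, float, str]]:
        if node.kind == "terminal":
            yield prob, node.payoff_cost, node.payoff_effect, node.label
            return
        for p, child in node.children:
            yield from walk(child, prob * p)

    yield from walk(tree, 1.0)


def run_strategies(params: ModelParams, key: UtilityKey) -> list[StrategyResult]:
    """Roll back both strategy trees under the given parameters and key."""
    results = []
    for strategy in STRATEGIES:
        cost, effect = rollback(build_strategy_tree(params, key, strategy))
        results.append(
            StrategyResult(strategy=strategy, expected_cost=cost, expected_effect=effect)
        )
    return results


def calibrate_residuals(
    params: ModelParams, target_cost_operative: float, target_cost_conservative: float
) -> ModelParams:
    """Set per-arm residual costs so rollback reproduces published arm costs.

    Expected cost is additive in the residual, so the residual is simply the
    gap between the published arm cost and the literal (residual-free)
    rollback cost.
    """
    zeroed = replace_params(
        params, residual_cost_operative=0.0, residual_cost_conservative=0.0
    )
    # any valid key works: costs do not depend on utilities
    flat = UtilityKey(means={c: 0.5 for c in CLASSES})
    by_name = {r.strategy: r.expected_cost for r in run_strategies(zeroed, flat)}
    return replace_params(
        params,
        residual_cost_operative=target_cost_operative - by_name["reconstruction"],
        residual_cost_conservative=target_cost_conservative - by_name["conservative"],
    )


def tree_to_dict(node: TreeNode) -> dict:
    if node.kind == "terminal":
        return {
            "kind": "terminal",
            "label": node.label,
            "payoff_cost": node.payoff_cost,
            "payoff_effect": node.payoff_effect,
            "activity_class": node.activity_class.name if node.activity_class else None,
        }
    return {
        "kind": "chance",
        "label": node.label,
        "children": [[p, tree_to_dict(child)] for p, child in node.children],
    }


def tree_from_dict(data: dict) -> TreeNode:
    if data["kind"] == "terminal":
        cls = data.get("activity_class")
        return TreeNode(
            kind="terminal",
            label=data.get("label", ""),
            payoff_cost=float(data["payoff_cost"]),
            payoff_effect=float(data["payoff_effect"]),
            activity_class=ActivityClass[cls] if cls else None,
        )
    return TreeNode(
        kind="chance",
        label=data.get("label", ""),
        children=[(float(p), tree_from_dict(child)) for p, child in data["children"]],
    )


def tree_to_json(node: TreeNode, indent: int = 2) -> str:
    return json.dumps(tree_to_dict(node), indent=indent)


def render_tree(node: TreeNode, _prefix: str = "", _prob: float | None = None) -> str:
    """Indented text rendering of a tree for inspection."""
    head = f"{_prefix}"
    if _prob is not None:
        head += f"[p={_prob:g}] "
    if node.kind == "terminal":
        head += (
            f"{node.label or 'terminal'}: cost={node.payoff_cost:.2f}, "
            f"effect={node.payoff_effect:.4f}"
        )
        return head
    head += f"{node.label or 'chance'}"
    lines = [head]
    for p, child in node.children:
        lines.append(render_tree(child, _prefix + "  ", p))
    return "\n".join(lines)
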