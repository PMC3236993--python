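"""Incremental cost-effectiveness analysis, dominance, NMB and scenarios.

Supports any number of strategies with standard dominance handling:
strategies are ordered by cost; a strategy that is more expensive and no
more effective than another is (strongly) dominated, and extended
dominance prunes strategies that break ICER-chain monotonicity along the
efficiency frontier. Incremental quantities are computed between
successive frontier members from unrounded internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .tree import ModelParams, StrategyResult, replace_params, run_strategies
from .utilities import UtilityKey

__all__ = [
    "IncrementalRow",
    "NMBResult",
    "UNDEFINED",
    "DOMINATED",
    "EXT_DOMINATED",
    "incremental_table",
    "table_icer",
    "net_monetary_benefit",
    "worst_case_no_sequelae",
]

UNDEFINED = "undefined"
DOMINATED = "dominated"
EXT_DOMINATED = "extended-dominated"


@dataclass(frozen=True)
class IncrementalRow:
    """One strategy's row of the incremental cost-effectiveness table.

    ``icer`` is a float (USD/QALY vs the previous frontier strategy), one
    of the markers ``dominated`` / ``extended-dominated`` / ``undefined``,
    or None for the least costly frontier strategy.
    """

    strategy: str
    cost: float
    incr_cost: float | None
    effect: float
    incr_effect: float | None
    ce_ratio: float
    icer: float | str | None

    @property
    def on_frontier(self) -> bool:
        return self.icer not in (DOMINATED, EXT_DOMINATED)


@dataclass(frozen=True)
class NMBResult:
    strategy: str
    wtp: float
    nmb: float


def incremental_table(results: Sequence[StrategyResult]) -> list[IncrementalRow]:
    """Incremental analysis of two or more strategies, ordered by cost.

    Dominated strategies stay in the table (flagged) but are excluded from
    the frontier chain over which incremental differences are taken.
    """
    if len(results) < 2:
        raise ValueError("incremental analysis needs at least 2 strategies")
    for r in results:
        if r.expected_effect <= 0:
            raise ValueError(f"{r.strategy}: non-positive effect {r.expected_effect}")
    # deterministic order: by cost, then effect descending, then name
    ordered = sorted(
        results, key=lambda r: (r.expected_cost, -r.expected_effect, r.strategy)
    )

    dominated = set()
    for r in ordered:
        for other in ordered:
            if other is r:
                continue
            strictly_cheaper_no_worse = (
                other.expected_cost < r.expected_cost
                and other.expected_effect >= r.expected_effect
            )
            same_cost_better = (
                other.expected_cost == r.expected_cost
                and other.expected_effect > r.expected_effect
            )
            if strictly_cheaper_no_worse or same_cost_better:
                dominated.add(r.strategy)
                break

    # extended dominance: prune frontier members whose ICER exceeds the next
    # member's ICER until the ICER chain is non-decreasing
    frontier = [r for r in ordered if r.strategy not in dominated]
    ext_dominated: set[str] = set()
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        icers = [
            (frontier[i].expected_cost - frontier[i - 1].expected_cost)
            / (frontier[i].expected_effect - frontier[i - 1].expected_effect)
            for i in range(1, len(frontier))
        ]
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                ext_dominated.add(frontier[i + 1].strategy)
                frontier.pop(i + 1)
                changed = True
                break

    rows: list[IncrementalRow] = []
    prev: StrategyResult | None = None
    for r in ordered:
        ce_ratio = r.expected_cost / r.expected_effect
        if r.strategy in dominated:
            rows.append(
                IncrementalRow(r.strategy, r.expected_cost, None, r.expected_effect, None, ce_ratio, DOMINATED)
            )
            continue
        if r.strategy in ext_dominated:
            rows.append(
                IncrementalRow(r.strategy, r.expected_cost, None, r.expected_effect, None, ce_ratio, EXT_DOMINATED)
            )
            continue
        if prev is None:
            rows.append(
                IncrementalRow(r.strategy, r.expected_cost, None, r.expected_effect, None, ce_ratio, None)
            )
        else:
            d_cost = r.expected_cost - prev.expected_cost
            d_eff = r.expected_effect - prev.expected_effect
            icer: float | str = d_cost / d_eff if d_eff != 0 else UNDEFINED
            rows.append(
                IncrementalRow(r.strategy, r.expected_cost, d_cost, r.expected_effect, d_eff, ce_ratio, icer)
            )
        prev = r
    return rows


def table_icer(rows: Sequence[IncrementalRow]) -> float:
    """The ICER of the costliest frontier strategy (the headline number)."""
    for row in reversed(rows):
        if row.on_frontier and isinstance(row.icer, float):
            return row.icer
    raise ValueError("no defined frontier ICER in table")


def net_monetary_benefit(result: StrategyResult, wtp: float) -> NMBResult:
    """NMB = wtp * effect - cost."""
    if wtp < 0:
        raise ValueError(f"willingness to pay must be non-negative, got {wtp}")
    return NMBResult(
        strategy=result.strategy,
        wtp=wtp,
        nmb=wtp * result.expected_effect - result.expected_cost,
    )


def worst_case_no_sequelae(params: ModelParams, key: UtilityKey) -> list[IncrementalRow]:
    """Scenario with both sequelae probabilities forced to zero.

    All other parameters, including the residual calibration constants,
    are unchanged.
    """
    scenario = replace_params(params, p_seq_operative=0.0, p_seq_conservative=0.0)
    return incremental_table(run_strategies(scenario, key))
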