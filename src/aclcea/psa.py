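"""Monte Carlo probabilistic sensitivity analysis over utility parameters.

Per iteration, each class utility is drawn from a normal distribution
truncated to [0,1] by resampling, the draw is shared by both strategies
(common random numbers: both arms use the same transformation key), the
strategy trees' terminal effects are rebuilt from the sampled key and
rolled back. Costs are not sampled, so draw costs equal the deterministic
arm costs.

Reproducibility: each (seed, iteration) pair seeds an independent numpy
Generator, so draws are identical regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import CLASSES, ActivityClass
from .tree import (
    STRATEGIES,
    ModelParams,
    StrategyResult,
    TreeNode,
    build_strategy_tree,
    rollback,
)
from .utilities import UtilityKey

__all__ = [
    "PSASpec",
    "PSAResult",
    "CEACCurve",
    "DEFAULT_WTP_GRID",
    "sample_utility_key",
    "run_psa",
    "ceac",
    "scatter_export",
]

MAX_TRUNCATION_TRIES = 1000

#: 0 to 100,000 USD/QALY in steps of 1,000.
DEFAULT_WTP_GRID: tuple[float, ...] = tuple(float(w) for w in range(0, 100_001, 1000))


@dataclass(frozen=True)
class PSASpec:
    """Sampling specification: per-class (mean, sd) blocks, size and seed."""

    sampled_parameters: Mapping[ActivityClass, tuple[float, float]]
    n_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        params = {}
        for c, (mean, sd) in self.sampled_parameters.items():
            c = ActivityClass(c)
            if sd < 0:
                raise ValueError(f"negative SD for class {c.name}: {sd}")
            params[c] = (float(mean), float(sd))
        object.__setattr__(self, "sampled_parameters", params)

    @classmethod
    def from_key(cls, key: UtilityKey, n_iterations: int = 10_000, seed: int = 0) -> "PSASpec":
        return cls(
            sampled_parameters={c: (key.mean(c), key.sd(c)) for c in CLASSES},
            n_iterations=n_iterations,
            seed=seed,
        )


@dataclass(frozen=True)
class PSAResult:
    """Per-draw (cost, effect) per strategy plus summary statistics."""

    spec: PSASpec
    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_iterations, n_strategies)
    effects: np.ndarray  # (n_iterations, n_strategies)

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for j, s in enumerate(self.strategies):
            ce = self.costs[:, j] / self.effects[:, j]
            out[s] = {
                "mean_cost": float(self.costs[:, j].mean()),
                "mean_effect": float(self.effects[:, j].mean()),
                "sd_effect": float(self.effects[:, j].std(ddof=1)) if len(ce) > 1 else 0.0,
                "mean_ce_ratio": float(ce.mean()),
                "sd_ce_ratio": float(ce.std(ddof=1)) if len(ce) > 1 else 0.0,
            }
        return out


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability probabilities per WTP plus the mean-NMB frontier."""

    wtp_grid: tuple[float, ...]
    probabilities: Mapping[str, np.ndarray]  # per strategy, aligned with wtp_grid
    frontier: tuple[tuple[float, str, float], ...]  # (wtp, strategy, probability)

    def as_frame(self) -> pd.DataFrame:
        frontier_at = {w: s for w, s, _ in self.frontier}
        records = []
        for s, probs in self.probabilities.items():
            for w, p in zip(self.wtp_grid, probs):
                records.append(
                    {
                        "wtp": w,
                        "strategy": s,
                        "probability": float(p),
                        "on_frontier": frontier_at[w] == s,
                    }
                )
        return pd.DataFrame.from_records(records)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to [0,1] by resampling (capped)."""
    if sd == 0.0:
        if not (0.0 <= mean <= 1.0):
            raise ValueError(f"degenerate draw outside [0,1]: {mean}")
        return float(mean)
    for _ in range(MAX_TRUNCATION_TRIES):
        x = rng.normal(mean, sd)
        if 0.0 <= x <= 1.0:
            return float(x)
    raise RuntimeError(
        f"truncation failed after {MAX_TRUNCATION_TRIES} tries (mean={mean}, sd={sd})"
    )


def sample_utility_key(spec: PSASpec, iteration: int) -> UtilityKey:
    """Draw one utility key; deterministic in (spec.seed, iteration).

    Per-class draws are independent. The sampled key is NOT forced to be
    monotone (sampling noise may reorder adjacent classes), so the means
    are returned through an order-free container.
    """
    rng = np.random.default_rng([int(spec.seed), int(iteration)])
    means = {}
    for c in sorted(spec.sampled_parameters, key=int):
        mean, sd = spec.sampled_parameters[c]
        means[c] = _truncated_normal(rng, mean, sd)
    return _SampledKey(means)


class _SampledKey:
    """Utility key without the monotonicity invariant (PSA draws only)."""

    def __init__(self, means: Mapping[ActivityClass, float]) -> None:
        self.means = dict(means)
        self.sds: dict[ActivityClass, float] = {}

    def mean(self, c: ActivityClass) -> float:
        c = ActivityClass(c)
        if c not in self.means:
            raise KeyError(f"class {c.name} missing from utility key")
        return self.means[c]

    def sd(self, c: ActivityClass) -> float:
        return 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.mean(c) for c in CLASSES])


def _reroll_effect(node: TreeNode, key) -> float:
    """Re-evaluate expected effect with terminal utilities taken from ``key``."""
    if node.kind == "terminal":
        if node.activity_class is None:
            return node.payoff_effect
        return key.mean(node.activity_class)
    return sum(p * _reroll_effect(child, key) for p, child in node.children)


def run_psa(params: ModelParams, spec: PSASpec) -> PSAResult:
    """Monte Carlo PSA: per iteration, resample utilities and roll back.

    Costs do not depend on utilities, so each strategy's cost column is
    constant at its deterministic rollback value.
    """
    base_key = UtilityKey(means={c: spec.sampled_parameters[c][0] for c in CLASSES}) \
        if _monotone(spec) else _SampledKey(
            {c: spec.sampled_parameters[c][0] for c in CLASSES}
        )
    trees = {s: build_strategy_tree(params, base_key, s) for s in STRATEGIES}
    det_costs = {}
    for s, tree in trees.items():
        cost, _ = rollback(tree)
        det_costs[s] = cost

    n = spec.n_iterations
    costs = np.empty((n, len(STRATEGIES)))
    effects = np.empty((n, len(STRATEGIES)))
    for i in range(n):
        key = sample_utility_key(spec, i)
        for j, s in enumerate(STRATEGIES):
            costs[i, j] = det_costs[s]
            effects[i, j] = _reroll_effect(trees[s], key)
    return PSAResult(spec=spec, strategies=tuple(STRATEGIES), costs=costs, effects=effects)


def _monotone(spec: PSASpec) -> bool:
    means = [spec.sampled_parameters[c][0] for c in sorted(spec.sampled_parameters, key=int)]
    return all(b >= a for a, b in zip(means, means[1:]))


def ceac(psa: PSAResult, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> CEACCurve:
    """Cost-effectiveness acceptability curve and mean-NMB frontier.

    At each WTP, a strategy's acceptability is the fraction of draws in
    which it attains the maximal NMB (ties broken toward the less costly
    strategy); the frontier strategy is the argmax of mean NMB over draws.
    """
    grid = [float(w) for w in wtp_grid]
    if not grid:
        raise ValueError("empty willingness-to-pay grid")
    if any(w < 0 for w in grid):
        raise ValueError("willingness to pay must be non-negative")

    n, k = psa.costs.shape
    # deterministic tie-break toward the cheaper strategy: perturb the argmax
    # comparison by strategy order after sorting columns by deterministic cost
    mean_costs = psa.costs.mean(axis=0)
    cheap_order = np.argsort(mean_costs, kind="stable")

    probs = {s: np.empty(len(grid)) for s in psa.strategies}
    frontier: list[tuple[float, str, float]] = []
    for gi, w in enumerate(grid):
        nmb = w * psa.effects - psa.costs  # (n, k)
        best = np.full(n, -1, dtype=int)
        best_val = np.full(n, -np.inf)
        for j in cheap_order:  # first (cheapest) wins ties via strict >
            better = nmb[:, j] > best_val
            best[better] = j
            best_val[better] = nmb[better, j]
        counts = np.bincount(best, minlength=k)
        for j, s in enumerate(psa.strategies):
            probs[s][gi] = counts[j] / n
        mean_nmb = nmb.mean(axis=0)
        # frontier tie-break toward the cheaper strategy as well
        best_mean = mean_nmb.max()
        fj = next(j for j in cheap_order if mean_nmb[j] == best_mean)
        frontier.append((w, psa.strategies[fj], float(counts[fj] / n)))

    return CEACCurve(
        wtp_grid=tuple(grid),
        probabilities=probs,
        frontier=tuple(frontier),
    )


def scatter_export(psa: PSAResult) -> pd.DataFrame:
    """Cost-effectiveness plane points: one row per (iteration, strategy)."""
    records = []
    for j, s in enumerate(psa.strategies):
        for i in range(psa.spec.n_iterations):
            records.append(
                {
                    "iteration": i,
                    "strategy": s,
                    "cost": float(psa.costs[i, j]),
                    "effect": float(psa.effects[i, j]),
                }
            )
    return pd.DataFrame.from_records(records)
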