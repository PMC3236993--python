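"""Mapping of activity classes to utilities and calibration of the key.

The per-class utility means and SDs (the "transformation key") are a config
input. Because the source survey publishes only arm-level aggregates, the
shipped default key is produced by :func:`fit_utilities`, a constrained
least-squares calibration of a monotone key in [0,1]^5 against those
aggregates. The calibration is plumbing: it reproduces published arm-level
effects, not the survey's unpublished per-class values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .evidence import CLASSES, ActivityClass, ActivityDistribution

__all__ = [
    "UtilityKey",
    "EffectTargets",
    "FitResult",
    "shift_class_down",
    "shifted_distribution",
    "expected_utility",
    "fit_utilities",
]


@dataclass(frozen=True)
class UtilityKey:
    """Per-class utility mean and SD; means are monotone non-decreasing I..V."""

    means: Mapping[ActivityClass, float]
    sds: Mapping[ActivityClass, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        means = {ActivityClass(c): float(v) for c, v in self.means.items()}
        sds = {ActivityClass(c): float(v) for c, v in self.sds.items()}
        for c, v in means.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"mean utility for class {c.name} out of [0,1]: {v}")
        for c, v in sds.items():
            if v < 0:
                raise ValueError(f"negative SD for class {c.name}: {v}")
        ordered = sorted(means, key=int)
        for lo, hi in zip(ordered, ordered[1:]):
            if means[hi] < means[lo] - 1e-12:
                raise ValueError(
                    f"mean utilities must be non-decreasing: "
                    f"{lo.name}={means[lo]} > {hi.name}={means[hi]}"
                )
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    def mean(self, c: ActivityClass) -> float:
        c = ActivityClass(c)
        if c not in self.means:
            raise KeyError(f"class {c.name} missing from utility key")
        return self.means[c]

    def sd(self, c: ActivityClass) -> float:
        return self.sds.get(ActivityClass(c), 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.mean(c) for c in CLASSES])


@dataclass(frozen=True)
class EffectTargets:
    """Published arm-level expected effects used as calibration targets."""

    target_effect_operative: float
    target_effect_conservative: float

    def __post_init__(self) -> None:
        for v in (self.target_effect_operative, self.target_effect_conservative):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"target effect out of [0,1]: {v}")
        if self.target_effect_operative < self.target_effect_conservative:
            raise ValueError("operative target must be >= conservative target")


def shift_class_down(c: ActivityClass) -> ActivityClass:
    """One class lower after treatment failure; class I stays at I."""
    c = ActivityClass(c)
    if c not in CLASSES:
        raise ValueError(f"class {c.name} outside I..V")
    if c is ActivityClass.I:
        return ActivityClass.I
    return ActivityClass(int(c) - 1)


def shifted_distribution(dist: ActivityDistribution) -> ActivityDistribution:
    """Move every class's mass one class down (class I mass stays put)."""
    shifted = {c: 0.0 for c in CLASSES}
    for c in CLASSES:
        shifted[shift_class_down(c)] += dist[c]
    return ActivityDistribution.from_counts(shifted)


def expected_utility(dist: ActivityDistribution, key: UtilityKey) -> float:
    """Probability-weighted mean utility of a distribution under a key."""
    return float(sum(dist[c] * key.mean(c) for c in dist.classes()))


@dataclass(frozen=True)
class FitResult:
    """Calibrated key plus the residual of the fit against its targets."""

    key: UtilityKey
    achieved_effects: tuple[float, float]
    residuals: tuple[float, ...]
    objective: float


def fit_utilities(
    targets: EffectTargets,
    model: "ModelParams",  # noqa: F821 - forward ref, lazy import below
    *,
    worst_case_incr_effect: float | None = None,
    sds: Mapping[ActivityClass, float] | None = None,
) -> FitResult:
    """Calibrate a monotone utility key against published arm-level effects.

    Finds means ``u`` in [0,1]^5, non-decreasing I..V, minimizing the squared
    deviation of the model's arm-level expected effects from ``targets``
    (optionally also of the no-sequelae incremental effect from
    ``worst_case_incr_effect``), with a small ridge toward an equally spaced
    key to resolve the underdetermination (2-3 targets, 5 unknowns).
    Deterministic: fixed start, no randomness.

    Raises ``ValueError`` if the optimizer cannot produce a feasible
    monotone bounded key.
    """
    from .tree import run_strategies  # local import: tree depends on this module

    # Arm effects are linear in the mean-utility vector, so the model's
    # effect map is fully described by its action on the unit keys.
    rows = []
    for strategy_effects in _effect_weights(model, run_strategies):
        rows.append(strategy_effects)
    a_op, a_cons = rows
    design = [a_op, a_cons]
    b = [targets.target_effect_operative, targets.target_effect_conservative]
    if worst_case_incr_effect is not None:
        from .tree import replace_params

        wc = replace_params(model, p_seq_operative=0.0, p_seq_conservative=0.0)
        w_op, w_cons = _effect_weights(wc, run_strategies)
        design.append(w_op - w_cons)
        b.append(float(worst_case_incr_effect))
    design_m = np.array(design)
    b_v = np.array(b)

    anchor = np.linspace(0.3, 0.9, 5)
    ridge = 1e-8

    def objective(u: np.ndarray) -> float:
        resid = design_m @ u - b_v
        return float(resid @ resid + ridge * np.sum((u - anchor) ** 2))

    # monotonicity: u_{c+1} - u_c >= 0
    mono = LinearConstraint(np.diff(np.eye(5), axis=0), 0.0, np.inf)
    res = minimize(
        objective,
        x0=anchor,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * 5,
        constraints=[mono],
        options={"maxiter": 500, "ftol": 1e-16},
    )
    if not res.success:
        raise ValueError(f"utility calibration infeasible: {res.message}")
    u = np.clip(res.x, 0.0, 1.0)
    u = np.maximum.accumulate(u)  # enforce bounds/monotonicity exactly
    key = UtilityKey(
        means={c: float(u[i]) for i, c in enumerate(CLASSES)},
        sds=dict(sds) if sds else {},
    )
    achieved = design_m[:2] @ u
    residuals = design_m @ u - b_v
    return FitResult(
        key=key,
        achieved_effects=(float(achieved[0]), float(achieved[1])),
        residuals=tuple(float(r) for r in residuals),
        objective=float(residuals @ residuals),
    )


def _effect_weights(model, run_strategies) -> tuple[np.ndarray, np.ndarray]:
    """Per-class linear weights of each arm's expected effect.

    Rollback effects are linear in the terminal utilities, so the weight of
    class c is the difference of arm effects between the monotone step keys
    "1 from class c up" and "1 above class c" (step keys keep every
    intermediate key valid, unlike raw indicators).
    """

    def arm_effects(key: UtilityKey) -> np.ndarray:
        by_name = {r.strategy: r.expected_effect for r in run_strategies(model, key)}
        return np.array([by_name["reconstruction"], by_name["conservative"]])

    def step_key(threshold: int) -> UtilityKey:
        return UtilityKey(means={k: (1.0 if int(k) >= threshold else 0.0) for k in CLASSES})

    weights = np.zeros((2, 5))
    for j, c in enumerate(CLASSES):
        weights[:, j] = arm_effects(step_key(int(c))) - arm_effects(step_key(int(c) + 1))
    return weights[0], weights[1]
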