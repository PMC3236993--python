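"""Synthetic inputs with the statistical structure the analysis assumes.

Generates multi-study activity-count tables (multinomial per study-arm),
expert-survey utility draws per activity class (truncated normal), and
resource line-item lists summing to requested totals — so every pipeline
stage is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .costing import CostProfile, ResourceItem
from .evidence import ARMS, CLASSES, ActivityClass, ActivityDistribution, StudyArmRecord
from .utilities import UtilityKey

__all__ = [
    "SynthStudyConfig",
    "generate_studies",
    "generate_utility_survey",
    "generate_cost_items",
]


@dataclass(frozen=True)
class SynthStudyConfig:
    """Shape of a synthetic multi-study activity table."""

    n_studies: int
    class_probabilities: Mapping[str, ActivityDistribution]  # per arm
    n_range: tuple[int, int] = (20, 80)
    age_range: tuple[float, float] = (20.0, 40.0)
    followup_range: tuple[float, float] = (48.0, 144.0)
    seed: int = 0
    fractional_count_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        lo, hi = self.n_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid n_range {self.n_range}")
        for name, rng in (("age_range", self.age_range), ("followup_range", self.followup_range)):
            if rng[0] > rng[1]:
                raise ValueError(f"invalid {name} {rng}")
        for arm in self.class_probabilities:
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
        if not self.class_probabilities:
            raise ValueError("class_probabilities must cover at least one arm")


def generate_studies(cfg: SynthStudyConfig) -> list[StudyArmRecord]:
    """Draw per-study, per-arm multinomial activity counts; seeded.

    With probability ``fractional_count_prob`` per record, one unit of
    count is split into two halves across a class pair, mirroring the
    half-counts real study tables contain and exercising the real-valued
    count path.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[StudyArmRecord] = []
    for i in range(cfg.n_studies):
        for arm, dist in cfg.class_probabilities.items():
            n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
            counts_arr = rng.multinomial(n, dist.as_array()).astype(float)
            if rng.random() < cfg.fractional_count_prob:
                donors = np.flatnonzero(counts_arr >= 1)
                if len(donors) >= 1:
                    a = int(rng.choice(donors))
                    b = int(rng.integers(0, len(CLASSES)))
                    if a != b:
                        counts_arr[a] -= 0.5
                        counts_arr[b] += 0.5
            records.append(
                StudyArmRecord(
                    study_label=f"synth_{i + 1:03d}",
                    arm=arm,
                    n=float(n),
                    counts={c: float(counts_arr[j]) for j, c in enumerate(CLASSES)},
                    mean_age=float(rng.uniform(*cfg.age_range)),
                    follow_up=float(rng.uniform(*cfg.followup_range)),
                )
            )
    return records


def generate_utility_survey(
    mu: Mapping[ActivityClass, float],
    sigma: Mapping[ActivityClass, float],
    n_experts: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, UtilityKey]:
    """Simulate an expert utility survey and derive a key from it.

    Each expert rates each class; draws are normal(mu, sigma) truncated to
    [0,1] by resampling. The derived key holds per-class sample means and
    (ddof=1) sample SDs. Sample means of a truncated normal are not
    guaranteed monotone at small n, so the derived means are projected to
    the monotone cone (cumulative max) before building the key.
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in CLASSES:
        m, s = float(mu[c]), float(sigma[c])
        if s < 0:
            raise ValueError(f"negative sigma for class {c.name}")
        draws = np.full(n_experts, m) if s == 0 else _truncated(rng, m, s, n_experts)
        for e, d in enumerate(draws):
            rows.append({"expert": e, "activity_class": c.name, "utility": float(d)})
    frame = pd.DataFrame.from_records(rows)
    means = frame.groupby("activity_class", sort=False)["utility"].mean()
    sds = frame.groupby("activity_class", sort=False)["utility"].std(ddof=1).fillna(0.0)
    mono = np.maximum.accumulate([means[c.name] for c in CLASSES])
    key = UtilityKey(
        means={c: float(np.clip(mono[j], 0.0, 1.0)) for j, c in enumerate(CLASSES)},
        sds={c: float(sds[c.name]) for c in CLASSES},
    )
    return frame, key


def _truncated(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draws = rng.normal(mean, sd, size=size)
        good = draws[(draws >= 0.0) & (draws <= 1.0)]
        take = min(len(good), size - filled)
        out[filled : filled + take] = good[:take]
        filled += take
        if filled == size:
            return out
    raise RuntimeError(f"truncated sampling failed (mean={mean}, sd={sd})")


def generate_cost_items(
    profile_totals: Mapping[str, float],
    n_items: int = 8,
    seed: int = 0,
) -> dict[str, CostProfile]:
    """Random non-negative line items summing exactly to each total.

    Uses a Dirichlet split of each total; the last item absorbs float
    round-off so the profile-total invariant holds exactly.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(seed)
    profiles: dict[str, CostProfile] = {}
    for label, total in profile_totals.items():
        if total < 0:
            raise ValueError(f"profile {label!r}: negative total {total}")
        shares = rng.dirichlet(np.ones(n_items)) * total
        shares[-1] = total - shares[:-1].sum()
        items = tuple(
            ResourceItem(
                name=f"{label}_item_{j + 1}",
                quantity=1.0,
                unit_cost=float(shares[j]),
                line_cost=float(max(shares[j], 0.0)),
            )
            for j in range(n_items)
        )
        profiles[label] = CostProfile(label=label, items=items, total=float(total))
    return profiles
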