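"""Pooling of study-level activity-class evidence into arm distributions.

Study arms report, per Gottlob activity class I-V, how many patients ended
up in each class. Pooling sums raw counts across studies and normalizes by
the pooled sample size; summary covariates (age, follow-up) are pooled as
sample-size-weighted means.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ActivityClass",
    "CLASSES",
    "ActivityDistribution",
    "StudyArmRecord",
    "ARMS",
    "pool_activity",
    "pooled_n",
    "high_activity_share",
    "weighted_mean",
    "read_study_csv",
    "write_study_csv",
    "pooled_summary",
]

COUNT_TOL = 1e-6
PROP_TOL = 1e-9

ARMS = ("operative", "conservative")


class ActivityClass(IntEnum):
    """Ordinal post-injury activity level; ZERO is the theoretical floor."""

    ZERO = 0
    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5

    @classmethod
    def from_label(cls, label: str) -> "ActivityClass":
        label = str(label).strip().upper()
        try:
            return cls[label] if not label.isdigit() else cls(int(label))
        except (KeyError, ValueError):
            raise ValueError(f"unknown activity class {label!r}") from None


#: Classes that appear in pooled evidence (class 0 never occurs in study tables).
CLASSES: tuple[ActivityClass, ...] = (
    ActivityClass.I,
    ActivityClass.II,
    ActivityClass.III,
    ActivityClass.IV,
    ActivityClass.V,
)


@dataclass(frozen=True)
class ActivityDistribution:
    """Normalized proportions over activity classes I-V."""

    proportions: Mapping[ActivityClass, float]

    def __post_init__(self) -> None:
        props = {ActivityClass(c): float(p) for c, p in self.proportions.items()}
        for c, p in props.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"proportion for class {c.name} out of [0,1]: {p}")
        total = sum(props.values())
        if abs(total - 1.0) > PROP_TOL:
            raise ValueError(f"proportions sum to {total!r}, not 1 (tol {PROP_TOL})")
        object.__setattr__(self, "proportions", props)

    @classmethod
    def from_counts(cls, counts: Mapping[ActivityClass, float]) -> "ActivityDistribution":
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValueError("cannot normalize all-zero counts")
        raw = {ActivityClass(c): float(v) / total for c, v in counts.items()}
        # renormalize to absorb float round-off so the sum-to-1 invariant holds exactly
        s = sum(raw.values())
        return cls({c: v / s for c, v in raw.items()})

    def __getitem__(self, c: ActivityClass) -> float:
        return self.proportions.get(ActivityClass(c), 0.0)

    def as_array(self, classes: Sequence[ActivityClass] = CLASSES) -> np.ndarray:
        return np.array([self[c] for c in classes], dtype=float)

    def classes(self) -> tuple[ActivityClass, ...]:
        return tuple(sorted(self.proportions, key=int))


@dataclass(frozen=True)
class StudyArmRecord:
    """One study x treatment-arm row: per-class patient counts plus covariates.

    Fractional counts are legal (study tables contain e.g. 6.5 where a count
    was split between classes); counts must sum to ``n`` within ``COUNT_TOL``.
    """

    study_label: str
    arm: str
    n: float
    counts: Mapping[ActivityClass, float] = field(default_factory=dict)
    mean_age: float = float("nan")
    follow_up: float = float("nan")

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not self.n > 0:
            raise ValueError(f"n must be positive, got {self.n}")
        counts = {ActivityClass(c): float(v) for c, v in self.counts.items()}
        for c, v in counts.items():
            if v < 0:
                raise ValueError(f"negative count for class {c.name}: {v}")
        total = sum(counts.values())
        if abs(total - self.n) > COUNT_TOL:
            raise ValueError(
                f"{self.study_label}/{self.arm}: counts sum to {total}, expected n={self.n}"
            )
        object.__setattr__(self, "counts", counts)

    def distribution(self) -> ActivityDistribution:
        return ActivityDistribution.from_counts(self.counts)


def pool_activity(records: Iterable[StudyArmRecord], arm: str) -> ActivityDistribution:
    """Pool per-class counts across studies of one arm into a distribution.

    The pooled class proportion is (sum of class counts) / (sum of n), i.e.
    raw-count pooling of the constructed population, not an average of
    per-study proportions.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    rows = [r for r in records if r.arm == arm]
    if not rows:
        raise ValueError(f"no evidence: no records for arm {arm!r}")
    totals = {c: 0.0 for c in CLASSES}
    for r in rows:
        for c in CLASSES:
            totals[c] += r.counts.get(c, 0.0)
    return ActivityDistribution.from_counts(totals)


def pooled_n(records: Iterable[StudyArmRecord], arm: str | None = None) -> float:
    """Total pooled sample size, optionally restricted to one arm."""
    return sum(r.n for r in records if arm is None or r.arm == arm)


def high_activity_share(dist: ActivityDistribution) -> float:
    """Share of the distribution in the high-activity classes IV and V."""
    return dist[ActivityClass.IV] + dist[ActivityClass.V]


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Sample-size-weighted mean: sum(v*w) / sum(w)."""
    if len(values) != len(weights):
        raise ValueError(f"length mismatch: {len(values)} values vs {len(weights)} weights")
    if not values:
        raise ValueError("weighted_mean of empty sequence")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    v = np.asarray(values, dtype=float)
    return float(np.dot(v, w) / w.sum())


_CSV_FIELDS = (
    "study",
    "arm",
    "n",
    "class_I",
    "class_II",
    "class_III",
    "class_IV",
    "class_V",
    "age_years",
    "followup_months",
)


def read_study_csv(path: str | Path) -> list[StudyArmRecord]:
    """Read study-arm records from CSV.

    Expected columns: study, arm, n, class_I..class_V, age_years,
    followup_months. Raises ``ValueError`` with file/line context on
    malformed rows.
    """
    path = Path(path)
    records: list[StudyArmRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        missing = set(_CSV_FIELDS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                counts = {
                    c: float(row[f"class_{c.name}"]) for c in CLASSES
                }
                records.append(
                    StudyArmRecord(
                        study_label=row["study"],
                        arm=row["arm"].strip().lower(),
                        n=float(row["n"]),
                        counts=counts,
                        mean_age=float(row["age_years"]),
                        follow_up=float(row["followup_months"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no data rows")
    return records


def write_study_csv(records: Iterable[StudyArmRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for r in records:
            writer.writerow(
                [r.study_label, r.arm, r.n]
                + [r.counts.get(c, 0.0) for c in CLASSES]
                + [r.mean_age, r.follow_up]
            )


def pooled_summary(records: Sequence[StudyArmRecord]) -> dict:
    """Per-arm pooled distribution, n, and weighted age/follow-up.

    Returns a plain dict suitable for JSON serialization; percentages are
    kept unrounded (rounding is a formatting concern).
    """
    out: dict = {}
    for arm in ARMS:
        rows = [r for r in records if r.arm == arm]
        if not rows:
            continue
        dist = pool_activity(rows, arm)
        weights = [r.n for r in rows]
        out[arm] = {
            "n": pooled_n(rows, arm),
            "proportions": {c.name: dist[c] for c in CLASSES},
            "high_activity_share": high_activity_share(dist),
            "mean_age": weighted_mean([r.mean_age for r in rows], weights),
            "follow_up": weighted_mean([r.follow_up for r in rows], weights),
        }
    out["total_n"] = pooled_n(records)
    return out
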