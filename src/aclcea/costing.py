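"""Arm-level and complication-level direct costs from resource line items.

Line costs are authoritative: medication rows fold dosing frequency into
the line cost, so ``quantity * unit_cost`` is deliberately not enforced.
All amounts are carried as real USD; rounding to whole USD happens only in
report formatting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ResourceItem",
    "CostProfile",
    "profile_total",
    "complication_cost",
    "chf_to_usd",
    "read_resource_csv",
    "write_resource_csv",
]

TOTAL_TOL = 0.5  # USD


@dataclass(frozen=True)
class ResourceItem:
    """One resource line: name, quantity, unit cost and authoritative line cost."""

    name: str
    quantity: float
    unit_cost: float
    line_cost: float

    def __post_init__(self) -> None:
        if self.line_cost < 0:
            raise ValueError(f"{self.name}: negative line cost {self.line_cost}")
        if self.quantity < 0:
            raise ValueError(f"{self.name}: negative quantity {self.quantity}")


@dataclass(frozen=True)
class CostProfile:
    """A labelled list of resource items with a total that must match their sum."""

    label: str
    items: Sequence[ResourceItem] = field(default_factory=tuple)
    total: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if abs(self.total - profile_total(self.items)) > TOTAL_TOL:
            raise ValueError(
                f"profile {self.label!r}: total {self.total} != item sum "
                f"{profile_total(self.items)} (tol {TOTAL_TOL})"
            )

    @classmethod
    def from_items(cls, label: str, items: Iterable[ResourceItem]) -> "CostProfile":
        items = tuple(items)
        return cls(label=label, items=items, total=profile_total(items))


def profile_total(items: Iterable[ResourceItem]) -> float:
    """Arithmetic sum of line costs (empty list sums to 0)."""
    total = 0.0
    for item in items:
        if item.line_cost < 0:
            raise ValueError(f"{item.name}: negative line cost {item.line_cost}")
        total += item.line_cost
    return total


def complication_cost(inpatient: float, perioperative: float) -> float:
    """Total cost of a sequela episode: inpatient plus perioperative component."""
    if inpatient < 0 or perioperative < 0:
        raise ValueError("complication cost components must be non-negative")
    return inpatient + perioperative


def chf_to_usd(amount_chf: float, factor: float = 1.15) -> float:
    """Convert Swiss Francs to USD by dividing by the conversion factor."""
    if not factor > 0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return amount_chf / factor


_CSV_FIELDS = ("profile", "name", "quantity", "unit_cost", "line_cost")


def read_resource_csv(path: str | Path) -> dict[str, CostProfile]:
    """Read resource items grouped into cost profiles from CSV.

    Expected columns: profile, name, quantity, unit_cost, line_cost.
    """
    path = Path(path)
    grouped: dict[str, list[ResourceItem]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        missing = set(_CSV_FIELDS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                item = ResourceItem(
                    name=row["name"],
                    quantity=float(row["quantity"]),
                    unit_cost=float(row["unit_cost"]),
                    line_cost=float(row["line_cost"]),
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            grouped.setdefault(row["profile"], []).append(item)
    if not grouped:
        raise ValueError(f"{path}: no data rows")
    return {label: CostProfile.from_items(label, items) for label, items in grouped.items()}


def write_resource_csv(profiles: Iterable[CostProfile], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for profile in profiles:
            for item in profile.items:
                writer.writerow(
                    [profile.label, item.name, item.quantity, item.unit_cost, item.line_cost]
                )
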