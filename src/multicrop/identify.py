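"""Greedy identification and disaggregation of sequential cropping systems.

Per grid cell and water supply the procedure is:

1. *Enumerate*: every single crop, and every permitted pair/triple of
   growing periods with pairwise-disjoint month sets, is a candidate
   system; its physical area is the minimum of the member areas.
2. *Rank*: candidates sort by cropping frequency (triple before double
   before single), then by physical area (largest first), then by a
   deterministic lexicographic key.
3. *Allocate*: walking the ranked list once, each candidate is re-capped
   to the minimum *remaining* area of its members, that amount is
   subtracted from each member and from the cell's remaining cropland,
   and the system is recorded. Leftover crop areas fall through to their
   single-crop candidates, so the allocated areas partition the cropland
   whenever the inputs are consistent.

Rainfed and irrigated calendars are processed independently and never mix
within one system. When the total candidate area exceeds the cell's
cropland, the tail of the ranking is excluded; whether the marginal
system is truncated to the remaining cropland or dropped entirely is
configurable (``exclusion_mode``), and exclusions are counted per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

from .core import (
    AREA_EPSILON,
    CandidateSystem,
    CellAllocation,
    CellCalendar,
    GrowingPeriod,
    InvalidCellError,
    WATER_SUPPLIES,
    periods_disjoint,
)
from .taxonomy import CombinationRules, is_permitted_combination

EXCLUSION_MODES = ("truncate", "skip")


def merge_periods(periods: Iterable[GrowingPeriod]) -> list[GrowingPeriod]:
    """Sum areas of records sharing (crop, subcrop, water, start, end).

    Duplicate records describe the same field population split across
    input rows; merging makes the allocation independent of record order.
    The result is canonically sorted.
    """
    acc: dict[tuple, float] = {}
    for p in periods:
        k = (p.crop_id, p.subcrop, p.water, p.start_month, p.end_month)
        acc[k] = acc.get(k, 0.0) + p.area
    return [
        GrowingPeriod(c, s, w, sm, em, a)
        for (c, s, w, sm, em), a in sorted(acc.items())
    ]


def _calendar_order(members: tuple[GrowingPeriod, ...]) -> tuple[GrowingPeriod, ...]:
    return tuple(sorted(members, key=lambda m: (m.start_month, m.crop_id, m.subcrop)))


def enumerate_candidates(
    cell: CellCalendar,
    rules: CombinationRules,
    water: str | None = None,
) -> list[CandidateSystem]:
    """All feasible candidate systems of a cell (optionally one water supply).

    Zero-area candidates (below 1e-6 ha) are dropped. Disjointness of the
    atomic monthly calendar guarantees one cycle completes within 12
    months, so no extra cycle-length check is needed.
    """
    waters = (water,) if water is not None else WATER_SUPPLIES
    out: list[CandidateSystem] = []
    for w in waters:
        periods = [p for p in merge_periods(cell.periods_for(w)) if p.area > AREA_EPSILON]
        for r in range(1, rules.max_frequency + 1):
            for combo in combinations(periods, r):
                if not all(
                    periods_disjoint(a, b) for a, b in combinations(combo, 2)
                ):
                    continue
                if not is_permitted_combination([p.key for p in combo], rules):
                    continue
                area = min(p.area for p in combo)
                out.append(CandidateSystem(_calendar_order(combo), area))
    return out


def rank_candidates(candidates: Iterable[CandidateSystem]) -> list[CandidateSystem]:
    """Sort by frequency desc, area desc, then lexicographic system key.

    The key ties (equal frequency and area) deterministically so repeated
    runs and shuffled inputs yield identical allocations.
    """
    def tie_key(c: CandidateSystem) -> tuple:
        return tuple(
            sorted((m.crop_id, m.subcrop, m.start_month, m.end_month) for m in c.members)
        )

    return sorted(
        candidates,
        key=lambda c: (-c.frequency, -c.area, c.key, tie_key(c)),
    )


@dataclass
class GridDiagnostics:
    """Whole-grid allocation bookkeeping."""

    n_cells: int = 0
    total_cropland_ha: float = 0.0
    total_allocated_ha: float = 0.0
    total_harvested_ha: float = 0.0
    excluded_alternatives: int = 0
    cells_fully_allocated: int = 0
    per_cell_excluded: dict[int, int] = field(default_factory=dict)

    @property
    def unallocated_fraction(self) -> float:
        if self.total_cropland_ha <= 0:
            return 0.0
        return 1.0 - self.total_allocated_ha / self.total_cropland_ha

    @property
    def fully_allocated_share(self) -> float:
        return self.cells_fully_allocated / self.n_cells if self.n_cells else 0.0

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "total_cropland_ha": self.total_cropland_ha,
            "total_allocated_ha": self.total_allocated_ha,
            "total_harvested_ha": self.total_harvested_ha,
            "unallocated_fraction": self.unallocated_fraction,
            "excluded_alternatives": self.excluded_alternatives,
            "fully_allocated_share": self.fully_allocated_share,
        }


def allocate_cell(
    cell: CellCalendar,
    rules: CombinationRules,
    exclusion_mode: str = "truncate",
) -> CellAllocation:
    """Disaggregate one cell's cropland into cropping systems.

    Greedy pass over the ranked candidate list, per water supply. A
    candidate whose members were already consumed by a better-ranked
    system contributes nothing and counts as an excluded alternative; a
    candidate exceeding the remaining cropland is truncated to it
    (``exclusion_mode="truncate"``) or dropped (``"skip"``).
    """
    if exclusion_mode not in EXCLUSION_MODES:
        raise ValueError(f"exclusion_mode must be one of {EXCLUSION_MODES}")
    alloc = CellAllocation(cell.cell_id, cell.lat, cell.lon)
    for water in WATER_SUPPLIES:
        cropland = cell.cropland_for(water)
        if cropland < 0:
            raise InvalidCellError(f"cell {cell.cell_id}: negative cropland")
        candidates = rank_candidates(enumerate_candidates(cell, rules, water))
        remaining = {p: p.area for c in candidates for p in c.members}
        budget = cropland
        for cand in candidates:
            cap = min(remaining[m] for m in cand.members)
            if cap <= AREA_EPSILON or budget <= AREA_EPSILON:
                alloc.excluded_alternatives += 1
                continue
            if cap > budget + AREA_EPSILON:
                if exclusion_mode == "skip":
                    alloc.excluded_alternatives += 1
                    continue
                amount = budget
            else:
                amount = min(cap, budget)
            for m in cand.members:
                remaining[m] -= amount
            budget -= amount
            alloc.allocated.append(
                (CandidateSystem(cand.members, amount), amount)
            )
        alloc.unallocated[water] = max(budget, 0.0)
    return alloc


def allocate_grid(
    cells: Iterable[CellCalendar],
    rules: CombinationRules,
    exclusion_mode: str = "truncate",
) -> tuple[list[CellAllocation], GridDiagnostics]:
    """Allocate every cell independently; cells are processed in cell_id order.

    Returns the per-cell allocations plus grid-level diagnostics (global
    unallocated fraction, counts of excluded alternative systems, share
    of cells where every possible system was allocated).
    """
    diags = GridDiagnostics()
    out: list[CellAllocation] = []
    for cell in sorted(cells, key=lambda c: c.cell_id):
        try:
            alloc = allocate_cell(cell, rules, exclusion_mode)
        except Exception as exc:  # re-raise with cell context
            raise InvalidCellError(f"cell {cell.cell_id}: {exc}") from exc
        out.append(alloc)
        diags.n_cells += 1
        diags.total_cropland_ha += sum(
            cell.cropland_for(w) for w in WATER_SUPPLIES
        )
        diags.total_allocated_ha += alloc.physical_area()
        diags.total_harvested_ha += alloc.harvested_area()
        diags.excluded_alternatives += alloc.excluded_alternatives
        diags.per_cell_excluded[cell.cell_id] = alloc.excluded_alternatives
        if alloc.excluded_alternatives == 0:
            diags.cells_fully_allocated += 1
    return out, diags
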