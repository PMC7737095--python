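"""Potential for increasing cropping intensity on single-cropped land.

A hectare currently under a single crop qualifies for a second harvest
when the potential growing season of its cell (consecutive months with
favourable temperature and soil moisture for rainfed farming, the FAO-AEZ
LGP) exceeds the crop's actual growing season by at least the scenario's
gap: 2 months (scenario A2, a short second crop with no land-preparation
fallow) or 4 months (A4, a two-month second crop plus a two-month
fallow). The "minus" variants A2-/A4- additionally require low frost risk
(minimum monthly mean temperature >= 10 degC) and low drought risk
(coefficient of variation of annual rainfall < 19%). Both rainfed and
irrigated single systems are screened against the rainfed potential
season.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    AREA_EPSILON,
    CandidateSystem,
    CellAllocation,
    ClimateSummary,
    ScenarioConfig,
)


def actual_season_length(system: CandidateSystem) -> int:
    """Occupied months of a single-cropping system's sole member."""
    if system.frequency != 1:
        raise ValueError("actual_season_length applies to single systems only")
    return system.members[0].season_length


def low_frost_risk(climate: ClimateSummary, threshold: float = 10.0) -> bool:
    """Minimum monthly mean temperature at or above the threshold."""
    return climate.tmin_monthly_mean >= threshold


def low_drought_risk(climate: ClimateSummary, threshold: float = 19.0) -> bool:
    """Rainfall coefficient of variation strictly below the threshold."""
    return climate.precip_cv < threshold


@dataclass
class PotentialResult:
    """Qualifying single-cropped area under one scenario."""

    scenario: str
    per_cell: dict[int, float] = field(default_factory=dict)
    total_ha: float = 0.0
    single_area_ha: float = 0.0
    harvested_area_ha: float = 0.0

    @property
    def pct_of_single_area(self) -> float:
        if self.single_area_ha <= 0:
            return 0.0
        return 100.0 * self.total_ha / self.single_area_ha

    @property
    def pct_of_harvested_area(self) -> float:
        if self.harvested_area_ha <= 0:
            return 0.0
        return 100.0 * self.total_ha / self.harvested_area_ha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"cell_id": c, "additional_area_ha": v}
                for c, v in sorted(self.per_cell.items())
            ],
            columns=["cell_id", "additional_area_ha"],
        )

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "total_ha": self.total_ha,
            "pct_of_single_area": self.pct_of_single_area,
            "pct_of_harvested_area": self.pct_of_harvested_area,
        }


def cell_qualifies(
    climate: ClimateSummary | None, cfg: ScenarioConfig
) -> bool:
    """Risk screen for one cell (always true without ``risk_screen``)."""
    if not cfg.risk_screen:
        return True
    if climate is None:
        return False
    return low_frost_risk(climate, cfg.frost_threshold) and low_drought_risk(
        climate, cfg.cv_threshold
    )


def potential_area(
    allocations: Iterable[CellAllocation],
    lgp: Mapping[int, int],
    climate: Mapping[int, ClimateSummary],
    cfg: ScenarioConfig,
) -> PotentialResult:
    """Sum the single-cropped area qualifying for a second crop.

    ``lgp`` maps cell_id to the potential growing season in months (0-12);
    ``climate`` maps cell_id to the per-cell climate summary (required
    when the scenario screens risk). Cells missing from ``lgp`` raise, so
    grid mismatches surface instead of silently contributing zero.
    """
    result = PotentialResult(scenario=cfg.name)
    single_by_cell: dict[int, float] = {}
    harvested_by_cell: dict[int, float] = {}
    for alloc in allocations:
        singles = [
            (sys, area)
            for sys, area in alloc.allocated
            if sys.frequency == 1 and area > AREA_EPSILON
        ]
        single_by_cell[alloc.cell_id] = sum(a for _, a in singles)
        harvested_by_cell[alloc.cell_id] = alloc.harvested_area()
        if not singles:
            continue
        if alloc.cell_id not in lgp:
            raise KeyError(
                f"cell {alloc.cell_id} missing from the potential-season raster"
            )
        potential = int(lgp[alloc.cell_id])
        if cfg.risk_screen and alloc.cell_id not in climate:
            raise KeyError(
                f"cell {alloc.cell_id} missing from the climate summary"
            )
        if not cell_qualifies(climate.get(alloc.cell_id), cfg):
            continue
        qualifying = sum(
            area
            for sys, area in singles
            if potential - actual_season_length(sys) >= cfg.min_gap
        )
        if qualifying > 0:
            result.per_cell[alloc.cell_id] = qualifying
    # sum in cell_id order so the result is independent of input order
    result.total_ha = sum(result.per_cell[c] for c in sorted(result.per_cell))
    result.single_area_ha = sum(single_by_cell[c] for c in sorted(single_by_cell))
    result.harvested_area_ha = sum(
        harvested_by_cell[c] for c in sorted(harvested_by_cell)
    )
    return result
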