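"""Core domain types for cropping-system identification.

The calendar model is atomic, inclusive and circular: months are integers
1-12, a growing period from ``start_month`` to ``end_month`` occupies every
month of the inclusive circular range (Nov-Feb occupies {11, 12, 1, 2}).
Areas are physical hectares; a field is counted once in physical area no
matter how many harvests it yields, while harvested area counts one hectare
per harvest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RAINFED = "rainfed"
IRRIGATED = "irrigated"
WATER_SUPPLIES = (RAINFED, IRRIGATED)

#: areas below this (hectares) are treated as zero throughout
AREA_EPSILON = 1e-6


class InvalidCropError(ValueError):
    """An unknown crop id or sub-crop was referenced."""


class FormatError(ValueError):
    """An input record violates the dialect contract."""


class InvalidCellError(ValueError):
    """A cell's cropland or period areas are inconsistent."""


def months_in_period(start_month: int, end_month: int) -> frozenset[int]:
    """Inclusive circular month range as a set, e.g. (11, 2) -> {11,12,1,2}."""
    if not (1 <= start_month <= 12 and 1 <= end_month <= 12):
        raise FormatError(
            f"months must be in 1..12, got start={start_month} end={end_month}"
        )
    n = (end_month - start_month) % 12 + 1
    return frozenset((start_month - 1 + k) % 12 + 1 for k in range(n))


@dataclass(frozen=True, order=True)
class GrowingPeriod:
    """One sub-crop's calendar occupancy and physical area in a cell.

    ``water`` is either ``"rainfed"`` or ``"irrigated"``; calendars of the
    two water supplies come from different sources and are never mixed in
    one system.
    """

    crop_id: int
    subcrop: int
    water: str
    start_month: int
    end_month: int
    area: float

    def __post_init__(self) -> None:
        if self.water not in WATER_SUPPLIES:
            raise FormatError(f"unknown water supply {self.water!r}")
        if not (1 <= self.subcrop <= 5):
            raise FormatError(f"subcrop must be in 1..5, got {self.subcrop}")
        if not (self.area >= 0.0 and self.area == self.area and self.area != float("inf")):
            raise FormatError(f"area must be finite and >= 0, got {self.area}")
        months_in_period(self.start_month, self.end_month)  # validates range

    @property
    def months(self) -> frozenset[int]:
        return months_in_period(self.start_month, self.end_month)

    @property
    def season_length(self) -> int:
        """Number of occupied months (1-12)."""
        return len(self.months)

    @property
    def key(self) -> tuple[int, int]:
        return (self.crop_id, self.subcrop)


def months_occupied(period: GrowingPeriod) -> frozenset[int]:
    """Set of calendar months occupied by a growing period."""
    return period.months


def periods_disjoint(a: GrowingPeriod, b: GrowingPeriod) -> bool:
    """True iff two periods share no calendar month.

    Non-overlap is the temporal precondition for sequencing two crops on
    the same field; a harvest month and the successor's planting month may
    not coincide under the atomic-month model.
    """
    return not (a.months & b.months)


@dataclass
class CellCalendar:
    """All growing periods of one 30 arc-min grid cell.

    ``cropland`` maps water supply to the cell's physical cropland
    (hectares, fallow excluded). When a water supply is missing the
    allocator falls back to the sum of that supply's period areas, an
    upper bound under which no system is ever excluded for lack of land.
    """

    cell_id: int
    lat: float
    lon: float
    cropland: dict[str, float] = field(default_factory=dict)
    periods: list[GrowingPeriod] = field(default_factory=list)

    def __post_init__(self) -> None:
        for water, area in self.cropland.items():
            if water not in WATER_SUPPLIES:
                raise FormatError(f"unknown water supply {water!r}")
            if area < 0:
                raise InvalidCellError(
                    f"cell {self.cell_id}: negative cropland {area} ({water})"
                )

    def periods_for(self, water: str) -> list[GrowingPeriod]:
        return [p for p in self.periods if p.water == water]

    def cropland_for(self, water: str) -> float:
        """Physical cropland for one water supply (see class docstring)."""
        if water in self.cropland:
            return self.cropland[water]
        return sum(p.area for p in self.periods_for(water))


@dataclass(frozen=True)
class CandidateSystem:
    """An ordered sequence of 1-3 growing periods forming one system.

    ``area`` is the system's physical area: the minimum of the member
    areas, since every member occupies the same fields. Members are stored
    in calendar order (by start month) and all share one water supply with
    pairwise-disjoint month sets.
    """

    members: tuple[GrowingPeriod, ...]
    area: float

    def __post_init__(self) -> None:
        if not (1 <= len(self.members) <= 3):
            raise ValueError("a system has 1-3 members")
        waters = {m.water for m in self.members}
        if len(waters) != 1:
            raise ValueError("system members must share one water supply")
        for i, a in enumerate(self.members):
            for b in self.members[i + 1 :]:
                if a.months & b.months:
                    raise ValueError("system member months must be disjoint")

    @property
    def water(self) -> str:
        return self.members[0].water

    @property
    def frequency(self) -> int:
        return len(self.members)

    @property
    def key(self) -> tuple[tuple[int, int], ...]:
        """Order-independent identity: sorted member (crop_id, subcrop)."""
        return tuple(sorted(m.key for m in self.members))

    @property
    def label(self) -> str:
        """Stable readable key, e.g. ``ir:c03s01+c03s02``."""
        prefix = "ir" if self.water == IRRIGATED else "rf"
        body = "+".join(f"c{c:02d}s{s:02d}" for c, s in self.key)
        return f"{prefix}:{body}"


@dataclass
class CellAllocation:
    """Disaggregation of one cell's cropland into cropping systems."""

    cell_id: int
    lat: float
    lon: float
    allocated: list[tuple[CandidateSystem, float]] = field(default_factory=list)
    unallocated: dict[str, float] = field(default_factory=dict)
    excluded_alternatives: int = 0

    @property
    def unallocated_cropland(self) -> float:
        return sum(self.unallocated.values())

    def physical_area(self, water: str | None = None) -> float:
        """Total allocated physical area (hectares)."""
        return sum(
            a for sys, a in self.allocated if water is None or sys.water == water
        )

    def harvested_area(self, water: str | None = None) -> float:
        """Total harvested area: each system counts area x frequency."""
        return sum(
            a * sys.frequency
            for sys, a in self.allocated
            if water is None or sys.water == water
        )


@dataclass
class ClimateSummary:
    """Per-cell climate screens for the risk scenarios.

    ``monthly_tmean``: 12 monthly mean temperatures (deg C, Jan-Dec);
    ``precip_cv``: coefficient of variation of annual rainfall in percent.
    """

    monthly_tmean: tuple[float, ...] | None = None
    tmin_monthly_mean: float | None = None
    precip_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.monthly_tmean is not None:
            if len(self.monthly_tmean) != 12:
                raise FormatError("monthly_tmean needs exactly 12 values")
            self.tmin_monthly_mean = min(self.monthly_tmean)
        if self.tmin_monthly_mean is None:
            raise FormatError("either monthly_tmean or tmin_monthly_mean required")
        if self.precip_cv < 0:
            raise FormatError("precip_cv must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Rules for one intensification scenario.

    ``min_gap``: required difference (months) between the potential and
    the actual growing season before a second crop fits; ``risk_screen``
    additionally restricts to cells with low frost risk (minimum monthly
    mean temperature >= ``frost_threshold``) and low drought risk
    (rainfall CV < ``cv_threshold``).
    """

    name: str
    min_gap: int
    risk_screen: bool
    frost_threshold: float = 10.0
    cv_threshold: float = 19.0

    def __post_init__(self) -> None:
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")


#: the four scenarios: A2/A4 differ in the required season gap, the
#: "minus" variants add the frost & drought risk screen.
SCENARIOS: dict[str, ScenarioConfig] = {
    "A2": ScenarioConfig("A2", min_gap=2, risk_screen=False),
    "A4": ScenarioConfig("A4", min_gap=4, risk_screen=False),
    "A2minus": ScenarioConfig("A2minus", min_gap=2, risk_screen=True),
    "A4minus": ScenarioConfig("A4minus", min_gap=4, risk_screen=True),
}
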