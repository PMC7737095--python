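"""Synthetic MIRCA2000-like landscapes with planted ground truth.

Every cell is built from an explicit list of planted cropping systems, so
the true system composition is known exactly and pipeline recovery can be
checked end to end without downloading any external data set. The random
generator emulates the structural features of the real inputs — 26 crop
classes with sub-crops, a rainfed/irrigated split, contiguous circular
growing seasons, log-uniformly spread field areas, unimodal and bimodal
rainfall regimes — not crop growth or weather.

Recovery is guaranteed by construction: each cell and water supply
carries at most one annual multi-crop system; additional sole crops are
either perennials (which never enter sequences) or annuals whose growing
window intersects every other annual period, so no unplanned combination
is ever feasible and the greedy allocator must return exactly the
planted systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    CandidateSystem,
    CellAllocation,
    CellCalendar,
    ClimateSummary,
    GrowingPeriod,
    IRRIGATED,
    RAINFED,
    months_in_period,
)
from .grid_io import (
    write_climate_csv,
    write_growing_areas,
    write_lgp_csv,
    write_systems,
)
from .identify import merge_periods, rank_candidates
from .taxonomy import Taxonomy, load_taxonomy


@dataclass(frozen=True)
class PlantedSystem:
    """One system to plant: members are (crop_id, subcrop, start, end)."""

    members: tuple[tuple[int, int, int, int], ...]
    water: str
    area: float

    def to_candidate(self) -> CandidateSystem:
        periods = tuple(
            GrowingPeriod(c, s, self.water, sm, em, self.area)
            for c, s, sm, em in sorted(self.members, key=lambda m: (m[2], m[0], m[1]))
        )
        return CandidateSystem(periods, self.area)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic grid.

    Defaults describe a mixed agricultural landscape: most cells single
    cropped, roughly a third double cropped and a twentieth triple
    cropped, a fifth of cells in a bimodal-rainfall regime, multi-crop
    systems mostly irrigated, field areas log-uniform between 1e3 and
    1e5 ha (realistic populations for 30 arc-min cells). A single integer
    seed fully determines the grid.
    """

    n_cells: int = 100
    seed: int = 0
    p_fallow_cell: float = 0.05
    p_double: float = 0.30
    p_triple: float = 0.05
    bimodal_fraction: float = 0.20
    p_irrigated_multi: float = 0.60
    p_irrigated_single: float = 0.15
    p_rice_rice: float = 0.30
    p_extra_perennial: float = 0.30
    p_extra_annual: float = 0.30
    area_min_ha: float = 1e3
    area_max_ha: float = 1e5
    fallow_area_fraction: float = 0.0
    area_jitter: float = 0.0
    p_distractor: float = 0.0
    #: explicit per-cell planting menus; overrides the random draw
    menu: list[list[PlantedSystem]] | None = None


class InvalidSpecError(ValueError):
    """A planted system violates disjointness or water constraints."""


def build_cell(
    cell_id: int,
    lat: float,
    lon: float,
    planted: Sequence[PlantedSystem],
    fallow_area: dict[str, float] | None = None,
    distractors: Sequence[GrowingPeriod] = (),
) -> tuple[CellCalendar, CellAllocation]:
    """Materialize a calendar plus its ground-truth allocation.

    The calendar's periods are the union of the planted systems' member
    periods (areas of identical crop/season records merge); cropland per
    water supply is the sum of planted areas plus any fallow slack.
    """
    for ps in planted:
        sets = [months_in_period(sm, em) for _, _, sm, em in ps.members]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                if a & b:
                    raise InvalidSpecError(
                        f"cell {cell_id}: planted members overlap in months"
                    )
    periods = [m for ps in planted for m in ps.to_candidate().members]
    cropland: dict[str, float] = {}
    for ps in planted:
        cropland[ps.water] = cropland.get(ps.water, 0.0) + ps.area
    for water, extra in (fallow_area or {}).items():
        cropland[water] = cropland.get(water, 0.0) + extra
    cell = CellCalendar(
        cell_id, lat, lon,
        cropland=cropland,
        periods=merge_periods(periods) + list(distractors),
    )
    truth = CellAllocation(cell_id, lat, lon)
    candidates = [ps.to_candidate() for ps in planted]
    # allocation order: rainfed first, then irrigated, ranked within each
    ranked = [
        c
        for water in (RAINFED, IRRIGATED)
        for c in rank_candidates(x for x in candidates if x.water == water)
    ]
    truth.allocated = [(c, c.area) for c in ranked]
    truth.unallocated = {w: (fallow_area or {}).get(w, 0.0) for w in cropland}
    return cell, truth


def _snap(value: float) -> float:
    """Snap to the nearest 30 arc-min cell centre (x.25 / x.75 degrees)."""
    return round((value - 0.25) / 0.5) * 0.5 + 0.25


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_blocks(rng: np.random.Generator, k: int, bimodal: bool) -> list[tuple[int, int]]:
    """k pairwise-disjoint non-wrapping month windows for one system."""
    if k == 1:
        length = int(rng.integers(3, 9))
        start = int(rng.integers(1, 13))
        end = (start + length - 2) % 12 + 1
        return [(start, end)]
    if k == 2:
        bounds = ((3, 6), (9, 12)) if bimodal else ((1, 6), (7, 12))
    else:
        bounds = ((1, 4), (5, 8), (9, 12))
    blocks = []
    for lo, hi in bounds:
        start = int(rng.integers(lo, hi - 1))
        end = int(rng.integers(start + 1, hi + 1))
        blocks.append((start, end))
    return blocks


def _draw_crops(
    rng: np.random.Generator, k: int, taxonomy: Taxonomy, rice_rice: bool
) -> list[tuple[int, int]]:
    if rice_rice:
        return [(3, 1), (3, 2)][:k]
    pool = [c for c in taxonomy.annual_crop_ids]
    ids = rng.choice(pool, size=k, replace=False)
    return [(int(c), 1) for c in ids]


def generate_cell(
    spec: SyntheticSpec,
    cell_id: int,
    taxonomy: Taxonomy | None = None,
) -> tuple[CellCalendar, CellAllocation]:
    """Draw one cell; deterministic in (spec.seed, cell_id)."""
    taxonomy = taxonomy or load_taxonomy()
    rng = np.random.default_rng([spec.seed, cell_id])
    lat = _snap(rng.uniform(-50, 50))
    lon = _snap(rng.uniform(-180, 180))

    if spec.menu is not None:
        planted = spec.menu[cell_id]
        return build_cell(cell_id, lat, lon, planted)

    if rng.random() < spec.p_fallow_cell:
        cell = CellCalendar(
            cell_id, lat, lon,
            cropland={RAINFED: _log_uniform(rng, spec.area_min_ha, spec.area_max_ha)},
        )
        truth = CellAllocation(cell_id, lat, lon)
        truth.unallocated = dict(cell.cropland)
        return cell, truth

    bimodal = rng.random() < spec.bimodal_fraction
    u = rng.random()
    freq = 3 if u < spec.p_triple else (2 if u < spec.p_triple + spec.p_double else 1)
    water = (
        IRRIGATED
        if rng.random()
        < (spec.p_irrigated_multi if freq > 1 else spec.p_irrigated_single)
        else RAINFED
    )
    rice_rice = freq == 2 and water == IRRIGATED and rng.random() < spec.p_rice_rice
    crops = _draw_crops(rng, freq, taxonomy, rice_rice)
    blocks = _draw_blocks(rng, freq, bimodal)
    area = _log_uniform(rng, spec.area_min_ha, spec.area_max_ha)
    planted = [
        PlantedSystem(
            tuple((c, s, sm, em) for (c, s), (sm, em) in zip(crops, blocks)),
            water, area,
        )
    ]
    used_crops = {c for c, _ in crops}

    if rng.random() < spec.p_extra_perennial:
        pool = [c for c in taxonomy.perennial_crop_ids if c not in used_crops]
        crop = int(rng.choice(pool))
        used_crops.add(crop)
        planted.append(
            PlantedSystem(
                ((crop, 1, 1, 12),),
                RAINFED if rng.random() < 0.8 else IRRIGATED,
                _log_uniform(rng, spec.area_min_ha, spec.area_max_ha),
            )
        )
    if rng.random() < spec.p_extra_annual:
        # span window intersects every planted annual period of this water
        starts = [sm for _, _, sm, _ in planted[0].members]
        ends = [em for _, _, _, em in planted[0].members]
        span = (min(starts), max(ends)) if freq > 1 else (starts[0], ends[0])
        pool = [c for c in taxonomy.annual_crop_ids if c not in used_crops]
        crop = int(rng.choice(pool))
        planted.append(
            PlantedSystem(
                ((crop, 1, span[0], span[1]),),
                water,
                _log_uniform(rng, spec.area_min_ha, spec.area_max_ha),
            )
        )

    if spec.area_jitter > 0:
        planted = [
            replace(ps, area=ps.area * (1 + rng.uniform(-spec.area_jitter, spec.area_jitter)))
            for ps in planted
        ]

    fallow = None
    if spec.fallow_area_fraction > 0:
        fallow = {
            ps.water: ps.area * spec.fallow_area_fraction for ps in planted[:1]
        }

    distractors: list[GrowingPeriod] = []
    if rng.random() < spec.p_distractor:
        pool = [c for c in taxonomy.annual_crop_ids if c not in used_crops]
        crop = int(rng.choice(pool))
        distractors.append(GrowingPeriod(crop, 1, RAINFED, 1, 4, 0.0))

    return build_cell(cell_id, lat, lon, planted, fallow, distractors)


def climate_for_cell(
    spec: SyntheticSpec, cell_id: int, cell: CellCalendar
) -> tuple[int, ClimateSummary]:
    """LGP months and climate summary, consistent with the cell's regime.

    The potential season extends the longest planted season by 0-6
    months (capped at 12); monthly temperatures follow a latitude-driven
    seasonal cycle; rainfall CV spreads across the 19% drought screen so
    both outcomes occur.
    """
    rng = np.random.default_rng([spec.seed, cell_id, 7919])
    if cell.periods:
        base = max(p.season_length for p in cell.periods)
    else:
        base = int(rng.integers(0, 13))
    lgp = int(min(12, base + int(rng.integers(0, 7))))
    alat = abs(cell.lat)
    mean = 27.0 - 0.40 * alat + rng.normal(0, 2)
    amp = max(0.0, 2.0 + 0.55 * alat + rng.normal(0, 1))
    peak = 7 if cell.lat >= 0 else 1
    monthly = tuple(
        mean - amp * np.cos(2 * np.pi * (m - peak) / 12.0) for m in range(1, 13)
    )
    cv = float(rng.uniform(5, 35))
    return lgp, ClimateSummary(monthly_tmean=monthly, precip_cv=cv)


@dataclass
class SyntheticGrid:
    """A generated landscape with its ground truth."""

    spec: SyntheticSpec
    cells: list[CellCalendar] = field(default_factory=list)
    truths: list[CellAllocation] = field(default_factory=list)
    lgp: dict[int, int] = field(default_factory=dict)
    climate: dict[int, ClimateSummary] = field(default_factory=dict)


def generate_grid(spec: SyntheticSpec, taxonomy: Taxonomy | None = None) -> SyntheticGrid:
    """Draw all cells of a grid (in memory)."""
    taxonomy = taxonomy or load_taxonomy()
    n = len(spec.menu) if spec.menu is not None else spec.n_cells
    grid = SyntheticGrid(spec=spec)
    for cell_id in range(n):
        cell, truth = generate_cell(spec, cell_id, taxonomy)
        grid.cells.append(cell)
        grid.truths.append(truth)
        lgp, climate = climate_for_cell(spec, cell_id, cell)
        grid.lgp[cell_id] = lgp
        grid.climate[cell_id] = climate
    return grid


def write_grid(grid: SyntheticGrid, out_dir: str | Path) -> dict[str, Path]:
    """Write a grid in both I/O dialects plus LGP/climate and the truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "growing_areas_csv": out_dir / "growing_areas.csv",
        "cropland_csv": out_dir / "cropland.csv",
        "growing_areas_nc": out_dir / "growing_areas.nc",
        "lgp_csv": out_dir / "lgp.csv",
        "climate_csv": out_dir / "climate.csv",
    }
    write_growing_areas(
        grid.cells, paths["growing_areas_csv"], "long_csv",
        cropland_path=paths["cropland_csv"],
    )
    write_growing_areas(grid.cells, paths["growing_areas_nc"], "netcdf")
    write_lgp_csv(grid.lgp, paths["lgp_csv"])
    write_climate_csv(grid.climate, paths["climate_csv"])
    truth_paths = write_systems(grid.truths, out_dir / "truth")
    paths.update({f"truth_{k}": v for k, v in truth_paths.items()})
    return paths


def fig2_style_cell(cell_id: int = 0) -> tuple[CellCalendar, CellAllocation]:
    """A cell reproducing the canonical worked example.

    Rainfed soybean (Nov-Mar, 80 ha) is combinable with maize (Jun-Sep),
    millet (Jun-Aug) and barley (May-Sep); maize-soybean has the largest
    system area, so it must be selected as the only double system, the
    residual maize area (100 ha) must come out as a sole crop, and the
    smaller soybean doubles must be excluded.
    """
    maize, soybean, millet, barley = 2, 8, 6, 4
    planted = [
        PlantedSystem(((maize, 1, 6, 9), (soybean, 1, 11, 3)), RAINFED, 80.0),
        PlantedSystem(((maize, 1, 6, 9),), RAINFED, 100.0),
        PlantedSystem(((barley, 1, 5, 9),), RAINFED, 60.0),
        PlantedSystem(((millet, 1, 6, 8),), RAINFED, 50.0),
    ]
    return build_cell(cell_id, 0.25, 0.25, planted)
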