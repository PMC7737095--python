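"""Reading and writing the gridded inputs and outputs.

Two input dialects are supported for monthly growing areas:

* ``long_csv`` — one row per growing period with columns
  ``cell_id,lat,lon,crop_id,subcrop,water,start_month,end_month,area_ha``,
  plus an optional cropland sidecar
  (``cell_id,lat,lon,water,cropland_ha``) carrying each cell's physical
  cropland; cells present only in the sidecar are fallow-only.
* ``netcdf`` — a flat record-dimension layout (one record per growing
  period) plus a cell dimension for cropland, written as NETCDF3_CLASSIC
  through the scipy backend so round-trips are bit-exact.

Cells are centres of a 30 arc-min WGS84 grid; months are atomic,
inclusive and circular; all areas are hectares.

Output allocations are written as a CSV systems table (full member
calendars, so the table round-trips to allocation objects exactly) and a
NetCDF file with one physical-area layer per cropping system.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .core import (
    CandidateSystem,
    CellAllocation,
    CellCalendar,
    ClimateSummary,
    FormatError,
    GrowingPeriod,
    IRRIGATED,
    RAINFED,
    WATER_SUPPLIES,
)

NETCDF_KW = dict(engine="scipy", format="NETCDF3_CLASSIC")
DIALECTS = ("long_csv", "netcdf")

GROWING_AREA_COLUMNS = [
    "cell_id", "lat", "lon", "crop_id", "subcrop", "water",
    "start_month", "end_month", "area_ha",
]
CROPLAND_COLUMNS = ["cell_id", "lat", "lon", "water", "cropland_ha"]

_EARTH_RADIUS_M = 6_371_000.0


def _to_csv(df: pd.DataFrame, path) -> None:
    """CSV write with shortest-round-trip float formatting (bit-exact)."""
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))



def _read_csv(path) -> pd.DataFrame:
    """CSV read with exact (round-trip) float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def cell_area_ha(lat: float, resolution_deg: float = 0.5) -> float:
    """Area of a ``resolution_deg`` grid cell centred at ``lat``, in hectares."""
    half = math.radians(resolution_deg) / 2.0
    phi = math.radians(lat)
    band = math.sin(min(phi + half, math.pi / 2)) - math.sin(max(phi - half, -math.pi / 2))
    return _EARTH_RADIUS_M**2 * math.radians(resolution_deg) * band / 1e4


def _period_from_row(row: Mapping) -> GrowingPeriod:
    try:
        return GrowingPeriod(
            crop_id=int(row["crop_id"]),
            subcrop=int(row["subcrop"]),
            water=str(row["water"]),
            start_month=int(row["start_month"]),
            end_month=int(row["end_month"]),
            area=float(row["area_ha"]),
        )
    except (FormatError, ValueError) as exc:
        raise FormatError(
            f"cell {row.get('cell_id')}, crop {row.get('crop_id')}: {exc}"
        ) from exc


def _assemble_cells(
    records: pd.DataFrame,
    cropland: pd.DataFrame | None,
    mask_fraction: float | None,
) -> list[CellCalendar]:
    cells: dict[int, CellCalendar] = {}

    def cell_for(cell_id: int, lat: float, lon: float) -> CellCalendar:
        if cell_id not in cells:
            cells[cell_id] = CellCalendar(cell_id, lat, lon)
        return cells[cell_id]

    if cropland is not None:
        for row in cropland.to_dict("records"):
            water = str(row["water"])
            if water not in WATER_SUPPLIES:
                raise FormatError(
                    f"cell {row['cell_id']}: unknown water supply {water!r}"
                )
            cell = cell_for(int(row["cell_id"]), float(row["lat"]), float(row["lon"]))
            cell.cropland[water] = cell.cropland.get(water, 0.0) + float(
                row["cropland_ha"]
            )
    for row in records.to_dict("records"):
        cell = cell_for(int(row["cell_id"]), float(row["lat"]), float(row["lon"]))
        cell.periods.append(_period_from_row(row))

    out = sorted(cells.values(), key=lambda c: c.cell_id)
    if mask_fraction is not None:
        kept = []
        for cell in out:
            total = sum(p.area for p in cell.periods)
            if total > mask_fraction * cell_area_ha(cell.lat):
                kept.append(cell)
        out = kept
    return out


def read_growing_areas(
    path: str | Path,
    dialect: str = "long_csv",
    cropland_path: str | Path | None = None,
    mask_fraction: float | None = None,
) -> list[CellCalendar]:
    """Read a monthly growing-area file into per-cell calendars.

    ``mask_fraction`` optionally drops cells whose total crop area is at
    or below that fraction of the grid-cell area (the reproduction
    setting is 0.01); default keeps every cell.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"dialect must be one of {DIALECTS}")
    if dialect == "long_csv":
        try:
            records = _read_csv(path)
        except pd.errors.EmptyDataError:
            records = pd.DataFrame(columns=GROWING_AREA_COLUMNS)
        if records.empty:
            records = pd.DataFrame(columns=GROWING_AREA_COLUMNS)
        missing = set(GROWING_AREA_COLUMNS) - set(records.columns)
        if missing and len(records):
            raise FormatError(f"missing columns: {sorted(missing)}")
        cropland = _read_csv(cropland_path) if cropland_path else None
        return _assemble_cells(records, cropland, mask_fraction)
    with xr.open_dataset(path, **{"engine": "scipy"}) as ds:
        records, cropland = _frames_from_netcdf(ds)
    return _assemble_cells(records, cropland, mask_fraction)


def write_growing_areas(
    cells: Iterable[CellCalendar],
    path: str | Path,
    dialect: str = "long_csv",
    cropland_path: str | Path | None = None,
) -> None:
    """Write calendars in one of the two dialects (inverse of reading)."""
    cells = sorted(cells, key=lambda c: c.cell_id)
    records = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id, "lat": c.lat, "lon": c.lon,
                "crop_id": p.crop_id, "subcrop": p.subcrop, "water": p.water,
                "start_month": p.start_month, "end_month": p.end_month,
                "area_ha": p.area,
            }
            for c in cells
            for p in sorted(c.periods)
        ],
        columns=GROWING_AREA_COLUMNS,
    )
    cropland = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id, "lat": c.lat, "lon": c.lon,
                "water": w, "cropland_ha": a,
            }
            for c in cells
            for w, a in sorted(c.cropland.items())
        ],
        columns=CROPLAND_COLUMNS,
    )
    if dialect == "long_csv":
        _to_csv(records, path)
        if cropland_path is not None:
            _to_csv(cropland, cropland_path)
        return
    if dialect != "netcdf":
        raise FormatError(f"dialect must be one of {DIALECTS}")
    ds = _netcdf_from_frames(records, cropland, cells)
    ds.to_netcdf(path, **NETCDF_KW)


def _netcdf_from_frames(
    records: pd.DataFrame, cropland: pd.DataFrame, cells: list[CellCalendar]
) -> xr.Dataset:
    water_code = {RAINFED: 0, IRRIGATED: 1}
    data = {}
    if len(records):
        for col in ("cell_id", "crop_id", "subcrop", "start_month", "end_month"):
            data[col] = ("record", records[col].to_numpy(np.int32))
        data["water_code"] = (
            "record", records["water"].map(water_code).to_numpy(np.int32)
        )
        data["lat"] = ("record", records["lat"].to_numpy(np.float64))
        data["lon"] = ("record", records["lon"].to_numpy(np.float64))
        data["area_ha"] = ("record", records["area_ha"].to_numpy(np.float64))
    data["cell_cell_id"] = ("cell", np.array([c.cell_id for c in cells], np.int32))
    data["cell_lat"] = ("cell", np.array([c.lat for c in cells], np.float64))
    data["cell_lon"] = ("cell", np.array([c.lon for c in cells], np.float64))
    for w in WATER_SUPPLIES:
        data[f"cropland_{w}"] = (
            "cell",
            np.array([c.cropland.get(w, np.nan) for c in cells], np.float64),
        )
    ds = xr.Dataset(data)
    ds.attrs["conventions"] = "multicrop flat growing-period records, areas in ha"
    return ds


def _frames_from_netcdf(ds: xr.Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    water_name = {0: RAINFED, 1: IRRIGATED}
    if "area_ha" in ds:
        records = pd.DataFrame(
            {
                "cell_id": ds["cell_id"].values.astype(int),
                "lat": ds["lat"].values,
                "lon": ds["lon"].values,
                "crop_id": ds["crop_id"].values.astype(int),
                "subcrop": ds["subcrop"].values.astype(int),
                "water": [water_name[int(w)] for w in ds["water_code"].values],
                "start_month": ds["start_month"].values.astype(int),
                "end_month": ds["end_month"].values.astype(int),
                "area_ha": ds["area_ha"].values,
            }
        )
    else:
        records = pd.DataFrame(columns=GROWING_AREA_COLUMNS)
    rows = []
    for i, cell_id in enumerate(ds["cell_cell_id"].values):
        for w in WATER_SUPPLIES:
            v = float(ds[f"cropland_{w}"].values[i])
            if not np.isnan(v):
                rows.append(
                    {
                        "cell_id": int(cell_id),
                        "lat": float(ds["cell_lat"].values[i]),
                        "lon": float(ds["cell_lon"].values[i]),
                        "water": w,
                        "cropland_ha": v,
                    }
                )
    return records, pd.DataFrame(rows, columns=CROPLAND_COLUMNS)


# ---------------------------------------------------------------------------
# LGP raster


def load_lgp_table(path: str | Path | None = None) -> pd.DataFrame:
    """The FAO-AEZ 16-class -> months conversion table."""
    if path is None:
        from importlib import resources

        text = (resources.files("multicrop") / "data" / "lgp_classes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return pd.DataFrame(raw["classes"])


def convert_lgp_classes(
    classes: np.ndarray | Iterable[int], table: pd.DataFrame | None = None
) -> np.ndarray:
    """Convert FAO-AEZ LGP classes (1-16) to months (0-12)."""
    table = table if table is not None else load_lgp_table()
    mapping = dict(zip(table["lgp_class"].astype(int), table["months"].astype(int)))
    arr = np.asarray(list(classes) if not isinstance(classes, np.ndarray) else classes)
    out = np.empty(arr.shape, dtype=np.int64)
    for idx, v in np.ndenumerate(arr):
        v = int(v)
        if v not in mapping:
            raise FormatError(f"unknown LGP class {v}")
        out[idx] = mapping[v]
    return out


def write_lgp_csv(lgp: Mapping[int, int], path: str | Path) -> None:
    pd.DataFrame(
        [{"cell_id": c, "lgp_months": int(m)} for c, m in sorted(lgp.items())],
        columns=["cell_id", "lgp_months"],
    ).to_csv(path, index=False)


def read_lgp_csv(path: str | Path) -> dict[int, int]:
    df = _read_csv(path)
    out = {}
    for row in df.to_dict("records"):
        m = int(row["lgp_months"])
        if not 0 <= m <= 12:
            raise FormatError(f"cell {row['cell_id']}: LGP months {m} out of 0..12")
        out[int(row["cell_id"])] = m
    return out


# ---------------------------------------------------------------------------
# Climate summary

_MONTH_COLS = [f"tmean_{m:02d}" for m in range(1, 13)]


def write_climate_csv(climate: Mapping[int, ClimateSummary], path: str | Path) -> None:
    rows = []
    for cell_id, c in sorted(climate.items()):
        row = {"cell_id": cell_id, "precip_cv_pct": c.precip_cv}
        if c.monthly_tmean is not None:
            row.update(dict(zip(_MONTH_COLS, c.monthly_tmean)))
        else:
            row.update({col: c.tmin_monthly_mean for col in _MONTH_COLS})
        rows.append(row)
    pd.DataFrame(rows, columns=["cell_id", *_MONTH_COLS, "precip_cv_pct"]).to_csv(
        path, index=False
    )


def read_climate_csv(path: str | Path) -> dict[int, ClimateSummary]:
    df = _read_csv(path)
    out = {}
    for row in df.to_dict("records"):
        out[int(row["cell_id"])] = ClimateSummary(
            monthly_tmean=tuple(float(row[c]) for c in _MONTH_COLS),
            precip_cv=float(row["precip_cv_pct"]),
        )
    return out


# ---------------------------------------------------------------------------
# Allocations (cropping-system output)


def _members_str(system: CandidateSystem) -> str:
    return ";".join(
        f"{m.crop_id}:{m.subcrop}:{m.start_month}:{m.end_month}"
        for m in system.members
    )


def allocations_to_frame(allocations: Iterable[CellAllocation]) -> pd.DataFrame:
    """Long systems table: one row per allocated system per cell."""
    rows = []
    for a in sorted(allocations, key=lambda x: x.cell_id):
        for system, area in a.allocated:
            rows.append(
                {
                    "cell_id": a.cell_id, "lat": a.lat, "lon": a.lon,
                    "water": system.water, "system_key": system.label,
                    "frequency": system.frequency,
                    "members": _members_str(system), "area_ha": area,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "lat", "lon", "water", "system_key",
            "frequency", "members", "area_ha",
        ],
    )


def frame_to_allocations(
    df: pd.DataFrame,
    unallocated: pd.DataFrame | None = None,
) -> list[CellAllocation]:
    """Inverse of :func:`allocations_to_frame` (exact round-trip)."""
    cells: dict[int, CellAllocation] = {}
    for row in df.to_dict("records"):
        cell_id = int(row["cell_id"])
        if cell_id not in cells:
            cells[cell_id] = CellAllocation(cell_id, float(row["lat"]), float(row["lon"]))
        members = tuple(
            GrowingPeriod(
                int(c), int(s), str(row["water"]), int(sm), int(em),
                float(row["area_ha"]),
            )
            for c, s, sm, em in (
                tuple(part.split(":")) for part in str(row["members"]).split(";")
            )
        )
        system = CandidateSystem(members, float(row["area_ha"]))
        cells[cell_id].allocated.append((system, float(row["area_ha"])))
    if unallocated is not None:
        for row in unallocated.to_dict("records"):
            cell_id = int(row["cell_id"])
            if cell_id not in cells:
                cells[cell_id] = CellAllocation(
                    cell_id, float(row["lat"]), float(row["lon"])
                )
            cells[cell_id].unallocated[str(row["water"])] = float(
                row["unallocated_ha"]
            )
            if "excluded_alternatives" in row:
                cells[cell_id].excluded_alternatives = int(
                    row["excluded_alternatives"]
                )
    return [cells[k] for k in sorted(cells)]


def _sanitize(label: str) -> str:
    return label.replace(":", "_").replace("+", "_")


def write_systems(
    allocations: Iterable[CellAllocation], out_dir: str | Path
) -> dict[str, Path]:
    """Write an allocation set to ``out_dir``.

    Produces ``systems.csv`` (full table, exact round-trip via
    :func:`read_systems`), ``unallocated.csv`` and ``systems.nc`` (one
    physical-area layer per cropping system over the cell dimension).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    allocations = sorted(allocations, key=lambda a: a.cell_id)
    table = allocations_to_frame(allocations)
    paths = {
        "systems_csv": out_dir / "systems.csv",
        "unallocated_csv": out_dir / "unallocated.csv",
        "systems_nc": out_dir / "systems.nc",
    }
    _to_csv(table, paths["systems_csv"])
    unalloc_df = pd.DataFrame(
        [
            {
                "cell_id": a.cell_id, "lat": a.lat, "lon": a.lon, "water": w,
                "unallocated_ha": v,
                "excluded_alternatives": a.excluded_alternatives,
            }
            for a in allocations
            for w, v in sorted(a.unallocated.items())
        ],
        columns=[
            "cell_id", "lat", "lon", "water", "unallocated_ha",
            "excluded_alternatives",
        ],
    )
    _to_csv(unalloc_df, paths["unallocated_csv"])

    cell_ids = [a.cell_id for a in allocations]
    index = {c: i for i, c in enumerate(cell_ids)}
    layers: dict[str, np.ndarray] = {}
    for a in allocations:
        for system, area in a.allocated:
            name = _sanitize(system.label)
            if name not in layers:
                layers[name] = np.zeros(len(cell_ids), np.float64)
            layers[name][index[a.cell_id]] += area
    data = {
        "cell_id": ("cell", np.array(cell_ids, np.int32)),
        "lat": ("cell", np.array([a.lat for a in allocations], np.float64)),
        "lon": ("cell", np.array([a.lon for a in allocations], np.float64)),
    }
    for name in sorted(layers):
        data[name] = ("cell", layers[name])
    ds = xr.Dataset(data)
    ds.attrs["conventions"] = "one physical-area layer (ha) per cropping system"
    ds.to_netcdf(paths["systems_nc"], **NETCDF_KW)
    return paths


def read_systems(out_dir: str | Path) -> list[CellAllocation]:
    """Read back an allocation set written by :func:`write_systems`."""
    out_dir = Path(out_dir)
    try:
        table = _read_csv(out_dir / "systems.csv")
    except pd.errors.EmptyDataError:
        table = pd.DataFrame()
    try:
        unalloc = _read_csv(out_dir / "unallocated.csv")
    except (FileNotFoundError, pd.errors.EmptyDataError):
        unalloc = None
    if table.empty:
        table = allocations_to_frame([])
    return frame_to_allocations(table, unalloc)
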