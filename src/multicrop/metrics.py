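"""Cropping-intensity arithmetic and report tabulations.

Cropping intensity (harvest frequency) is harvested area divided by
physical area; values above 1 indicate multiple cropping. Report tables
follow the field's convention: systems keyed by cropping frequency
(single/double/triple), the signature of member crop groups, and water
supply; regional tables aggregate cell totals over an arbitrary region
map (e.g. World Bank geographic or income groups).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .core import CellAllocation
from .taxonomy import GROUP_DISPLAY, GROUP_LABELS, Taxonomy

FREQUENCY_NAMES = {1: "single", 2: "double", 3: "triple"}


def cropping_intensity(harvested: float, physical: float) -> float:
    """Harvested area / physical area (both hectares, physical > 0)."""
    if physical <= 0:
        raise ValueError("cropping intensity undefined for physical area <= 0")
    return harvested / physical


def percent_shortfall(reported: float, reference: float) -> float:
    """Relative under-reporting of ``reported`` vs ``reference`` in percent."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return (reference - reported) / reference * 100.0


def group_signature(crop_ids: Iterable[int], taxonomy: Taxonomy) -> str:
    """Report label for a system's member crop groups.

    The distinct member groups, in canonical order, joined with " / ";
    monoculture sequences (e.g. rice-rice) report under the single group.
    """
    groups = {taxonomy.crop_group(c) for c in crop_ids}
    ordered = [g for g in GROUP_LABELS if g in groups]
    return " / ".join(GROUP_DISPLAY[g] for g in ordered)


def tabulate_systems(
    allocations: Iterable[CellAllocation], taxonomy: Taxonomy
) -> pd.DataFrame:
    """Global physical area by (frequency, group signature, water supply).

    Rows partition the total allocated area; the frame carries one row
    per occurring combination with columns ``frequency``, ``cropping``,
    ``signature``, ``water`` and ``area_ha``.
    """
    acc: dict[tuple[int, str, str], float] = {}
    for alloc in allocations:
        for system, area in alloc.allocated:
            sig = group_signature((c for c, _ in system.key), taxonomy)
            k = (system.frequency, sig, system.water)
            acc[k] = acc.get(k, 0.0) + area
    rows = [
        {
            "frequency": f,
            "cropping": FREQUENCY_NAMES[f],
            "signature": sig,
            "water": water,
            "area_ha": area,
        }
        for (f, sig, water), area in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows, columns=["frequency", "cropping", "signature", "water", "area_ha"]
    )


def systems_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Sub-totals per cropping frequency plus the grand total (hectares)."""
    if table.empty:
        return pd.DataFrame(columns=["cropping", "area_ha", "share_pct"])
    sub = table.groupby("cropping", sort=False)["area_ha"].sum()
    total = float(table["area_ha"].sum())
    rows = [
        {"cropping": name, "area_ha": float(sub.get(name, 0.0)),
         "share_pct": 100.0 * float(sub.get(name, 0.0)) / total if total else 0.0}
        for name in ("single", "double", "triple")
    ]
    rows.append({"cropping": "total", "area_ha": total, "share_pct": 100.0})
    return pd.DataFrame(rows)


def aggregate_by_region(
    cell_values: Mapping[int, float],
    regions: Mapping[int, str],
    value_name: str = "area_ha",
) -> pd.DataFrame:
    """Sum per-cell values over region labels.

    Cells missing from ``regions`` report under ``"unassigned"`` so the
    labelled rows always close against the global total.
    """
    acc: dict[str, float] = {}
    for cell_id, value in cell_values.items():
        label = regions.get(cell_id, "unassigned")
        acc[label] = acc.get(label, 0.0) + value
    return pd.DataFrame(
        [{"region": k, value_name: v} for k, v in sorted(acc.items())],
        columns=["region", value_name],
    )


def allocation_physical_by_cell(
    allocations: Iterable[CellAllocation], multi_only: bool = False
) -> dict[int, float]:
    """Per-cell allocated physical area, optionally multi-cropping only."""
    return {
        a.cell_id: sum(
            area for sys, area in a.allocated if not multi_only or sys.frequency > 1
        )
        for a in allocations
    }
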