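from __future__ import annotations

import numpy as np
import pytest

from multicrop.core import CellCalendar, GrowingPeriod, IRRIGATED, RAINFED
from multicrop.taxonomy import load_rules, load_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def rules(taxonomy):
    return load_rules(taxonomy=taxonomy)


def random_messy_cell(
    rng: np.random.Generator,
    cell_id: int = 0,
    max_periods: int = 6,
    annual_ids=(1, 2, 3, 6, 7, 8, 9, 10, 15, 16, 17, 21, 26),
) -> CellCalendar:
    """A cell with independently drawn periods: overlaps, shared crops,
    under-sized cropland — deliberately harder than the planted grids."""
    n = int(rng.integers(1, max_periods + 1))
    periods = []
    for _ in range(n):
        crop = int(rng.choice(annual_ids))
        start = int(rng.integers(1, 13))
        length = int(rng.integers(1, 9))
        end = (start + length - 2) % 12 + 1
        periods.append(
            GrowingPeriod(
                crop,
                1 if crop != 3 else int(rng.integers(1, 4)),
                RAINFED if rng.random() < 0.7 else IRRIGATED,
                start,
                end,
                float(np.round(rng.uniform(10, 5000), 3)),
            )
        )
    total = {
        w: sum(p.area for p in periods if p.water == w)
        for w in (RAINFED, IRRIGATED)
    }
    # cropland sometimes under-sized so the exclusion machinery engages
    cropland = {
        w: float(np.round(t * rng.uniform(0.3, 1.2), 3))
        for w, t in total.items()
        if t > 0
    }
    return CellCalendar(cell_id, 0.25, 0.25, cropland=cropland, periods=periods)
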