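"""Independent brute-force reference for the greedy allocator.

Deliberately shares no code path with the implementation: month sets are
integer bitmasks, areas are exact ``fractions.Fraction``, candidate
enumeration is redone from scratch at every allocation step, and the
next system is chosen by re-applying the ranking rule (frequency, then
the system's *original* physical area, then the lexicographic key) to
the candidates that still have positive remaining area.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

from multicrop.core import CellCalendar
from multicrop.taxonomy import CombinationRules, is_permitted_combination

EPS = Fraction(1, 10**6)


def _mask(start: int, end: int) -> int:
    m, bit = 0, start
    while True:
        m |= 1 << (bit - 1)
        if bit == end:
            return m
        bit = bit % 12 + 1


def oracle_allocate(
    cell: CellCalendar,
    rules: CombinationRules,
    exclusion_mode: str = "truncate",
):
    """Return {water: [(sorted (crop,subcrop) key, Fraction area), ...]}."""
    out: dict[str, list[tuple[tuple, Fraction]]] = {}
    for water in ("rainfed", "irrigated"):
        merged: dict[tuple, Fraction] = {}
        months: dict[tuple, int] = {}
        for p in cell.periods_for(water):
            k = (p.crop_id, p.subcrop, p.start_month, p.end_month)
            merged[k] = merged.get(k, Fraction(0)) + Fraction(p.area)
            months[k] = _mask(p.start_month, p.end_month)
        merged = {k: a for k, a in merged.items() if a > EPS}

        feasible = []
        for r in (1, 2, 3):
            for combo in combinations(sorted(merged), r):
                if any(
                    months[a] & months[b] for a, b in combinations(combo, 2)
                ):
                    continue
                if not is_permitted_combination([k[:2] for k in combo], rules):
                    continue
                original = min(merged[k] for k in combo)
                key = tuple(sorted(k[:2] for k in combo))
                feasible.append((combo, r, original, key))

        remaining = dict(merged)
        budget = Fraction(cell.cropland_for(water))
        chosen: list[tuple[tuple, Fraction]] = []
        done = set()
        while True:
            live = [
                f
                for f in feasible
                if f[0] not in done
                and min(remaining[k] for k in f[0]) > EPS
            ]
            if not live or budget <= EPS:
                break
            combo, r, original, key = min(
                live, key=lambda f: (-f[1], -f[2], f[3], f[0])
            )
            cap = min(remaining[k] for k in combo)
            if cap > budget + EPS:
                if exclusion_mode == "skip":
                    done.add(combo)
                    continue
                amount = budget
            else:
                amount = min(cap, budget)
            for k in combo:
                remaining[k] -= amount
            budget -= amount
            done.add(combo)
            chosen.append((key, amount))
        out[water] = chosen
    return out
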