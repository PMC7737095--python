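"""Core algorithm: candidate enumeration, ranking, greedy disaggregation."""

from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multicrop.core import (
    CellCalendar,
    GrowingPeriod,
    InvalidCellError,
    RAINFED,
    months_occupied,
    periods_disjoint,
)
from multicrop.identify import (
    allocate_cell,
    allocate_grid,
    enumerate_candidates,
    merge_periods,
    rank_candidates,
)
from multicrop.synthetic import fig2_style_cell

from .conftest import random_messy_cell
from .oracle import oracle_allocate

MAIZE, SOYBEAN, WHEAT, BARLEY, MILLET = 2, 8, 1, 4, 6


def rf(crop, start, end, area, subcrop=1):
    return GrowingPeriod(crop, subcrop, RAINFED, start, end, area)


class TestCalendar:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (11, 2, {11, 12, 1, 2}),
            (6, 9, {6, 7, 8, 9}),
            (3, 3, {3}),
            (1, 12, set(range(1, 13))),
        ],
    )
    def test_months_occupied(self, start, end, expected):
        assert months_occupied(rf(MAIZE, start, end, 1.0)) == expected

    @pytest.mark.parametrize(
        "a,b,disjoint",
        [
            ((11, 3), (4, 10), True),
            ((11, 2), (2, 6), False),   # share February
            ((12, 2), (3, 11), True),   # wrap-around
            ((6, 9), (6, 9), False),
        ],
    )
    def test_periods_disjoint(self, a, b, disjoint):
        pa, pb = rf(MAIZE, *a, 1.0), rf(SOYBEAN, *b, 1.0)
        assert periods_disjoint(pa, pb) is disjoint

    @settings(derandomize=True, max_examples=100)
    @given(start=st.integers(1, 12), end=st.integers(1, 12))
    def test_month_sets_are_contiguous_circular(self, start, end):
        months = sorted(months_occupied(rf(MAIZE, start, end, 1.0)))
        n = (end - start) % 12 + 1
        assert len(months) == n
        as_set = set(months)
        m = start
        for _ in range(n):
            assert m in as_set
            m = m % 12 + 1


class TestEnumerate:
    def test_min_area_rule(self, rules):
        cell = CellCalendar(
            0, 0.25, 0.25,
            periods=[rf(MAIZE, 6, 9, 100.0), rf(SOYBEAN, 11, 3, 80.0)],
        )
        cands = enumerate_candidates(cell, rules)
        by_key = {c.key: c.area for c in cands}
        assert by_key[((MAIZE, 1),)] == 100.0
        assert by_key[((SOYBEAN, 1),)] == 80.0
        assert by_key[((MAIZE, 1), (SOYBEAN, 1))] == 80.0
        assert len(cands) == 3

    def test_overlapping_crops_make_no_double(self, rules):
        cell = CellCalendar(
            0, 0.25, 0.25,
            periods=[rf(MAIZE, 5, 9, 100.0), rf(MILLET, 6, 8, 50.0)],
        )
        cands = enumerate_candidates(cell, rules)
        assert sorted(c.frequency for c in cands) == [1, 1]

    def test_three_doubles_with_soybean(self, rules):
        cell, _ = fig2_style_cell()
        doubles = [
            c for c in enumerate_candidates(cell, rules)
            if c.frequency == 2 and (SOYBEAN, 1) in c.key
        ]
        assert len(doubles) == 3

    def test_zero_area_candidates_dropped(self, rules):
        cell = CellCalendar(
            0, 0.25, 0.25,
            periods=[rf(MAIZE, 6, 9, 100.0), rf(SOYBEAN, 11, 3, 0.0)],
        )
        keys = {c.key for c in enumerate_candidates(cell, rules)}
        assert keys == {((MAIZE, 1),)}


class TestRanking:
    def test_frequency_before_area(self, rules):
        triple = CellCalendar(
            0, 0.25, 0.25,
            periods=[
                rf(MAIZE, 1, 3, 5.0), rf(SOYBEAN, 5, 7, 5.0),
                rf(WHEAT, 9, 11, 5.0), rf(MILLET, 4, 4, 500.0),
                rf(BARLEY, 8, 8, 500.0),
            ],
        )
        ranked = rank_candidates(enumerate_candidates(triple, rules))
        assert ranked[0].frequency == 3
        assert ranked[0].area == 5.0

    def test_area_descending_within_frequency(self, rules):
        cell = CellCalendar(
            0, 0.25, 0.25,
            periods=[
                rf(MAIZE, 1, 4, 80.0), rf(SOYBEAN, 6, 10, 80.0),
                rf(WHEAT, 1, 4, 60.0), rf(MILLET, 6, 10, 60.0),
            ],
        )
        doubles = [
            c for c in rank_candidates(enumerate_candidates(cell, rules))
            if c.frequency == 2
        ]
        assert doubles[0].area >= doubles[-1].area
        assert doubles[0].key == ((MAIZE, 1), (SOYBEAN, 1))

    def test_lexicographic_tie_break(self, rules):
        cell = CellCalendar(
            0, 0.25, 0.25,
            periods=[rf(SOYBEAN, 1, 4, 50.0), rf(MAIZE, 1, 4, 50.0)],
        )
        ranked = rank_candidates(enumerate_candidates(cell, rules))
        assert [c.key for c in ranked] == [((MAIZE, 1),), ((SOYBEAN, 1),)]


class TestAllocateCell:
    def test_single_crop_cell(self, rules):
        cell = CellCalendar(
            0, 0.25, 0.25,
            cropland={RAINFED: 100.0},
            periods=[rf(MAIZE, 6, 9, 100.0)],
        )
        alloc = allocate_cell(cell, rules)
        assert len(alloc.allocated) == 1
        assert alloc.allocated[0][1] == 100.0
        assert alloc.unallocated[RAINFED] == 0.0

    def test_double_consumes_both_crops_and_all_cropland(self, rules):
        # cropland 50 ha with two disjoint 50 ha crops: the double takes
        # everything, nothing is left for the single-crop candidates
        cell = CellCalendar(
            0, 0.25, 0.25,
            cropland={RAINFED: 50.0},
            periods=[rf(MAIZE, 1, 4, 50.0), rf(SOYBEAN, 6, 9, 50.0)],
        )
        alloc = allocate_cell(cell, rules)
        assert [(s.key, a) for s, a in alloc.allocated] == [
            (((MAIZE, 1), (SOYBEAN, 1)), 50.0)
        ]
        assert alloc.unallocated[RAINFED] == 0.0

    def test_fig2_narrative(self, rules):
        cell, truth = fig2_style_cell()
        alloc = allocate_cell(cell, rules)
        doubles = [(s, a) for s, a in alloc.allocated if s.frequency == 2]
        assert len(doubles) == 1
        assert doubles[0][0].key == ((MAIZE, 1), (SOYBEAN, 1))
        assert doubles[0][1] == 80.0
        singles = {s.key[0]: a for s, a in alloc.allocated if s.frequency == 1}
        assert singles[(MAIZE, 1)] == 100.0  # residual maize as sole crop
        assert singles[(BARLEY, 1)] == 60.0
        assert singles[(MILLET, 1)] == 50.0
        assert alloc.unallocated[RAINFED] == 0.0
        assert alloc.excluded_alternatives >= 2  # the smaller soybean doubles

    def test_truncate_vs_skip_exclusion_modes(self, rules):
        cell = CellCalendar(
            0, 0.25, 0.25,
            cropland={RAINFED: 30.0},
            periods=[rf(MAIZE, 1, 4, 50.0), rf(SOYBEAN, 6, 9, 50.0)],
        )
        truncated = allocate_cell(cell, rules, "truncate")
        assert [(s.frequency, a) for s, a in truncated.allocated] == [(2, 30.0)]
        assert truncated.unallocated[RAINFED] == 0.0

        skipped = allocate_cell(cell, rules, "skip")
        # skip mode drops every over-budget system whole: the 50 ha double
        # and both 50 ha singles all exceed the 30 ha budget
        assert skipped.allocated == []
        assert skipped.unallocated[RAINFED] == 30.0
        assert skipped.excluded_alternatives == 3

    def test_invalid_exclusion_mode(self, rules):
        with pytest.raises(ValueError):
            allocate_cell(CellCalendar(0, 0.25, 0.25), rules, "explode")

    def test_negative_cropland_signals(self, rules):
        with pytest.raises(Exception):
            cell = CellCalendar(0, 0.25, 0.25, cropland={RAINFED: -5.0})


class TestConservation:
    def test_area_conservation_on_messy_cells(self, rules):
        rng = np.random.default_rng(2024)
        for i in range(300):
            cell = random_messy_cell(rng, cell_id=i)
            alloc = allocate_cell(cell, rules)
            for water in cell.cropland:
                allocated = sum(
                    a for s, a in alloc.allocated if s.water == water
                )
                assert allocated + alloc.unallocated[water] == pytest.approx(
                    cell.cropland[water], abs=1e-6
                )

    def test_per_crop_conservation(self, rules):
        rng = np.random.default_rng(7)
        for i in range(200):
            cell = random_messy_cell(rng, cell_id=i)
            alloc = allocate_cell(cell, rules)
            merged = merge_periods(cell.periods)
            for p in merged:
                consumed = sum(
                    a
                    for s, a in alloc.allocated
                    for m in s.members
                    if m.key == p.key and m.water == p.water and m.months == p.months
                )
                assert consumed <= p.area + 1e-6

    def test_harvested_identity_when_complete(self, rules):
        # ample cropland: every period is fully consumed, so the harvested
        # area equals the sum of the period areas
        rng = np.random.default_rng(99)
        for i in range(100):
            cell = random_messy_cell(rng, cell_id=i)
            cell.cropland = {}  # fall back to the sum-of-areas upper bound
            alloc = allocate_cell(cell, rules)
            assert alloc.harvested_area() == pytest.approx(
                sum(p.area for p in cell.periods), rel=1e-9
            )


class TestOracleAgreement:
    def test_greedy_matches_bruteforce(self, rules):
        rng = np.random.default_rng(1234)
        checked = 0
        for i in range(250):
            cell = random_messy_cell(rng, cell_id=i)
            for mode in ("truncate", "skip"):
                alloc = allocate_cell(cell, rules, mode)
                expected = oracle_allocate(cell, rules, mode)
                for water in ("rainfed", "irrigated"):
                    got = [
                        (s.key, a)
                        for s, a in alloc.allocated
                        if s.water == water
                    ]
                    want = [(k, float(a)) for k, a in expected[water]]
                    assert len(got) == len(want)
                    for (gk, ga), (wk, wa) in zip(got, want):
                        assert gk == wk
                        assert ga == pytest.approx(wa, abs=1e-6)
            checked += 1
        assert checked == 250


class TestDeterminism:
    def test_record_order_does_not_matter(self, rules):
        rng = np.random.default_rng(5)
        shuffler = random.Random(5)
        for i in range(50):
            cell = random_messy_cell(rng, cell_id=i)
            base = allocate_cell(cell, rules)
            shuffled = CellCalendar(
                cell.cell_id, cell.lat, cell.lon,
                cropland=dict(cell.cropland),
                periods=shuffler.sample(cell.periods, len(cell.periods)),
            )
            again = allocate_cell(shuffled, rules)
            assert [(s.key, s.water, a) for s, a in base.allocated] == [
                (s.key, s.water, a) for s, a in again.allocated
            ]
            assert base.unallocated == again.unallocated


class TestAllocateGrid:
    def test_single_cell_grid(self, rules):
        cell = CellCalendar(
            7, 0.25, 0.25, cropland={RAINFED: 10.0},
            periods=[rf(MAIZE, 6, 9, 10.0)],
        )
        allocations, diags = allocate_grid([cell], rules)
        assert len(allocations) == 1
        assert diags.n_cells == 1
        assert diags.total_allocated_ha == pytest.approx(10.0)

    def test_all_fallow_cell(self, rules):
        cell = CellCalendar(3, 0.25, 0.25, cropland={RAINFED: 40.0})
        allocations, diags = allocate_grid([cell], rules)
        assert allocations[0].allocated == []
        assert allocations[0].unallocated[RAINFED] == 40.0
        assert diags.unallocated_fraction == pytest.approx(1.0)

    def test_error_carries_cell_id(self, rules):
        bad = CellCalendar(42, 0.25, 0.25)
        bad.cropland = {RAINFED: -1.0}  # bypass constructor validation
        with pytest.raises(InvalidCellError, match="42"):
            allocate_grid([bad], rules)
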