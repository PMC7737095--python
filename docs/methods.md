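# Methods

## Model and assumptions

The package models *sequential* multiple cropping only: two or three
crops grown one after another on the same field, with one full cycle
completing within 12 months. Intercropping (simultaneous cultivation)
and multi-year rotations are out of scope by design. The unit of
analysis is a 30 arc-min grid cell; within a cell, rainfed and irrigated
calendars come from different sources and are never mixed in one system.

The calendar is atomic, inclusive and circular: a growing period
occupies whole months, Nov–Feb occupies {11, 12, 1, 2}, and two periods
can be sequenced only if their month sets are disjoint. A consequence of
the atomic-month model is that a harvest month and the successor's
planting month may not coincide; this is the stricter of the two
possible readings and is applied uniformly.

Physical area counts a field once; harvested area counts one hectare per
harvest. Cropping intensity is harvested / physical and exceeds 1 only
where multiple cropping occurs. Fallow land, when present in the
cropland input, remains as unallocated cropland.

## The disaggregation algorithm

Per cell and water supply:

1. *Enumeration.* All singles, plus all pairs and triples of growing
   periods with pairwise-disjoint months that pass the combination
   rules. A candidate's physical area is the minimum of its member
   areas (the members occupy the same fields). Duplicate input records
   of one (crop, sub-crop, water, season) merge by summing areas before
   enumeration, which makes results independent of record order.
   Candidates below 1e-6 ha are dropped as float dust.
2. *Ranking.* By cropping frequency descending, then physical area
   descending. Ties (equal frequency and area) are broken by the
   lexicographic system key — the sorted member (crop, sub-crop) tuples,
   then the sorted member calendars. The tie rule is a package choice;
   some deterministic total order is required for reproducibility.
3. *Greedy allocation.* Walking the ranked list once, each candidate is
   re-capped to the minimum *remaining* area of its members; that
   amount is consumed from every member and from the cell's remaining
   cropland. A hectare of a crop therefore belongs to exactly one
   system, and leftover crop areas fall through to their sole-crop
   candidates. The ranking is computed once from the original areas and
   not revisited during the pass.

When the summed candidate areas exceed the cell's cropland the tail of
the ranking cannot be honoured. Two behaviours are provided because the
underlying data offer no way to decide which is right: the default
`truncate` allocates the marginal system at the remaining cropland;
`skip` drops any over-budget system whole. Both log the count of
excluded alternative systems per cell.

### Cropland input

Physical cropland per cell and water supply is an explicit input (a
sidecar CSV or NetCDF variables), because it is not derivable from
monthly growing areas alone — fields idle part of the year defeat any
max-over-months rule. When absent, the allocator falls back to the sum
of period areas, an upper bound under which no system is ever excluded;
the synthetic generator always writes exact cropland so conservation is
testable as an equality.

## Combination rules

The feasibility screen is config-driven (`data/combination_rules.yaml`).
The shipped defaults are a documented reconstruction of the three
unambiguous rules: paddy rice never sequences with upland or deep-water
rice; spring and winter varieties of one cereal are alternative
varieties, not a sequence; a crop may follow itself only where its
sub-crops encode true multiple seasons (paddy rice, sub-crops 1–3, so
rice–rice double and triple cropping is representable). Perennials
(sugar cane, oil palm, citrus, date palm, grapes, cocoa, coffee, other
perennials, fodder grasses) never join multi-crop sequences and always
allocate as sole-crop systems — sequential cropping requires the
preceding crop to be harvested within the cycle. Users can replace the
rule set wholesale with a YAML file.

## LGP conversion

The FAO-AEZ length-of-growing-period raster carries 16 classes, each 30
growing days wide apart from the first and last three. The shipped
class→month table applies floor(lower class bound / 30), capped at 12,
with the year-round classes mapping to 12 months and the no-season and
cold classes to 0. The exact upstream conversion table is not publicly
printed; the table is data, not code, and can be overridden.

## Intensification scenarios

A single-cropped hectare qualifies for a second harvest when
`LGP − actual season ≥ min_gap`, with `min_gap = 2` (scenario A2: a
short-cycle second crop, no land-preparation fallow) or `4` (A4: a
two-month second crop plus a two-month fallow). The risk-screened
variants A2-/A4- additionally require the cell to pass a frost screen
(minimum of the 12 monthly mean temperatures ≥ 10 °C, inclusive) and a
drought screen (coefficient of variation of annual rainfall < 19 %,
strict). Design choices made where the rules were genuinely open:

- The frost minimum is taken over *all* twelve monthly means, not only
  the would-be second season — the simplest reading of the criterion.
- The 19 % CV threshold is a configuration default, not recomputed from
  the input climate, so results do not drift with the climate sample.
- Both rainfed and irrigated single systems are screened against the
  *rainfed* potential growing season; irrigated land is not credited
  with a 12-month potential season.

These rules imply the nesting A4 ≤ A2, A2- ≤ A2 and
A4- ≤ min(A4, A2-), which the tests assert on every generated grid.

## Synthetic landscapes

The generator emulates the *structure* of the real inputs — crop
classes and sub-crops, rainfed/irrigated split, circular seasons,
log-uniform area magnitudes (10³–10⁵ ha, realistic field populations
for half-degree cells), unimodal and bimodal rainfall regimes with
matching season windows, latitude-driven monthly temperature cycles and
a rainfall-CV spread straddling the 19 % screen. Defaults: 100 cells,
5 % fallow-only cells, 30 % double- and 5 % triple-cropped cells, 20 %
bimodal cells, multi-crop systems irrigated with probability 0.6.

Recovery of the planted truth is guaranteed by construction: at most
one annual multi-crop system per cell and water supply, extra sole
crops either perennial (structurally unable to combine) or annual with
a growing window that intersects every other annual period. Optional
noise — area jitter, zero-area distractor crops — perturbs the inputs
without changing the planted identity. What passing recovery tests do
*not* show: behaviour on real landscapes where many systems share crops
in one cell and the ranking is genuinely ambiguous; those paths are
instead covered by a brute-force oracle comparison on randomly drawn
messy cells (overlaps, shared crops, under-sized cropland).

Climate fields are parameterized surfaces, not weather; the LGP is
drawn as the longest planted season plus 0–6 months, which produces a
realistic mix of cells above and below the scenario gaps but carries no
soil-moisture physics.

## Numerical choices

- Areas are float64 hectares; anything below 1e-6 ha is treated as
  zero throughout.
- CSV outputs use shortest-round-trip float formatting and are read
  back with exact parsing, so write/read cycles are bit-identical;
  NetCDF goes through NETCDF3_CLASSIC (float64) for the same reason.
- All summations that feed reported totals run in sorted cell order,
  making results independent of input ordering.
- Problem sizes in the test-suite and the acceptance script (grids of
  100–500 cells, 250–1000 random cells for property checks) were chosen
  as the smallest sizes at which every code path — triples, both water
  supplies, exclusions, all four scenarios — is exercised.

## Known limitations

- The combination-rule defaults and the LGP class table are
  reconstructions; both are data files meant to be replaced when the
  authoritative tables are available.
- The allocator models neither farmer preference nor economics: where
  several systems are feasible, the largest-area system wins by fiat.
- Whether over-budget systems should be truncated or dropped is not
  decidable from the inputs; both modes are provided and neither is
  asserted as canonical.
- No yield or production estimation: the intensification potential is
  an area, not a production figure.
- No re-gridding or projection support; inputs must share the grid.
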