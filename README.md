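# multicrop

Identify **sequential multiple-cropping systems** — two or three crops
grown one after another on the same field within a 12-month cycle — from
gridded monthly crop-specific growing areas and crop calendars, and
estimate the rule-based potential for increasing cropping intensity on
single-cropped land.

The package is aimed at land-use and agricultural-systems modellers who
work with MIRCA2000-style inputs: per grid cell (30 arc-min), per crop
class (26 classes, up to 5 sub-crops), per water supply (rainfed /
irrigated), a growing period (planting month to harvest month, circular)
and a physical area in hectares.

## Method

Cropping intensity is the ratio of harvested to physical area,

    CI = A_harvested / A_physical,

where a double-cropped hectare contributes two hectares to the harvested
area but one to the physical area. Per cell and water supply the
disaggregation proceeds in three steps:

1. **Enumerate** candidate systems: every single crop, and every
   permitted pair/triple of growing periods with pairwise-disjoint
   calendar months. A candidate's physical area is the *minimum* of its
   member areas. Combinations that are not technically feasible (paddy
   with upland rice, spring with winter varieties of one cereal,
   perennials in sequences) are excluded by a configurable rule set.
2. **Rank** candidates by cropping frequency (triple → double → single),
   then by physical area, then by a deterministic lexicographic key.
3. **Allocate** greedily down the ranked list: each system is re-capped
   to the minimum remaining area of its members, that amount is
   subtracted from the members and from the cell's remaining cropland.
   Leftover crop areas fall through to sole-crop systems, so allocated
   areas partition the cropland; over-budget systems are truncated or
   dropped (configurable) and counted as excluded alternatives.

On top of the resulting systems map, four scenarios quantify where a
second crop would fit on currently single-cropped land, comparing the
potential growing season (FAO-AEZ length of growing period, in months)
with the actual one: **A2** requires a gap of ≥ 2 months, **A4** of
≥ 4 months, and **A2-**/**A4-** additionally restrict to cells with low
frost risk (minimum monthly mean temperature ≥ 10 °C) and low drought
risk (CV of annual rainfall < 19 %).

A synthetic-landscape generator plants known system compositions into
MIRCA2000-like inputs, so the whole pipeline is testable end to end
without external downloads.

## Worked example

A cell with rainfed soybean (Nov–Mar, 80 ha), maize (Jun–Sep, 180 ha),
millet (Jun–Aug, 50 ha) and barley (May–Sep, 60 ha): soybean could pair
with any of the three disjoint summer crops, but maize–soybean has the
largest system area and wins; the excess maize becomes a sole crop.

```python
import multicrop as mc
from multicrop.synthetic import fig2_style_cell

cell, _ = fig2_style_cell()
alloc = mc.allocate_cell(cell, mc.load_rules())
for system, area in alloc.allocated:
    print(system.label, system.frequency, area)
print(round(mc.cropping_intensity(alloc.harvested_area(),
                                  alloc.physical_area()), 2))
```

prints

```
rf:c02s01+c08s01 2 80.0
rf:c02s01 1 100.0
rf:c04s01 1 60.0
rf:c06s01 1 50.0
1.28
```

i.e. one maize–soybean double system (80 ha), residual sole maize
(100 ha), sole barley and millet, and a cell cropping intensity of
370 ha harvested / 290 ha physical = 1.28.

The same workflow from the shell:

```sh
multicrop simulate --n-cells 100 --seed 1 --out data/
multicrop identify  --input data/growing_areas.csv --cropland data/cropland.csv --out systems/
multicrop report    --systems systems/ --out reports/
multicrop intensify --systems systems/ --lgp data/lgp.csv --climate data/climate.csv \
                    --scenario A2 --out potential/
```

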